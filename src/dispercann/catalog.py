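"""Previously discovered myocardium models at varying structural dispersion.

Sparse-regression model discovery on the standard human-myocardium
triaxial-shear + biaxial-extension dataset repeatedly lands on four-term
energies built from I2, the dispersed fourth invariants I4f*, I4n*, and the
coupling invariant I8fs.  This module collects the published weight columns
of those discovered models for three dispersion sweeps:

- ``SHEET_NORMAL_DISPERSION``: kappa_s = kappa_n swept, kappa_f = 0
- ``FIBER_DISPERSION``:        kappa_f swept, kappa_s = kappa_n = 0
- ``EQUAL_DISPERSION``:        kappa_f = kappa_s = kappa_n swept

Each sweep maps a dispersion level label ("0", "1/15", ..., "1/3") to a
:class:`CatalogModel` holding the kappa triple, the sparse weight map
(node index -> collapsed weight, or (inner, outer) pair), and the reported
mean goodness of fit.  These weight sets serve as generator models for
synthetic data and as worked examples for the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .constitutive import ModelWeights
from .dispersion import DispersionParams

__all__ = [
    "KAPPA_LEVELS",
    "CatalogModel",
    "SHEET_NORMAL_DISPERSION",
    "FIBER_DISPERSION",
    "EQUAL_DISPERSION",
    "get_model",
]

KAPPA_LEVELS = ("0", "1/15", "2/15", "1/5", "4/15", "1/3")


@dataclass(frozen=True)
class CatalogModel:
    """A published discovered model: kappas, sparse weights, reported fit."""

    kappas: DispersionParams
    terms: dict[int, float | tuple[float, float]]
    r2: float

    @property
    def weights(self) -> ModelWeights:
        return ModelWeights.from_terms(self.terms)


def _level(label: str) -> float:
    return float(Fraction(label))


def _sweep(which: str, columns: dict[str, tuple[dict, float]]) -> dict[str, CatalogModel]:
    out = {}
    for label, (terms, r2) in columns.items():
        k = _level(label)
        if which == "sn":
            kappas = DispersionParams(0.0, k, k)
        elif which == "f":
            kappas = DispersionParams(k, 0.0, 0.0)
        else:
            kappas = DispersionParams(k, k, k)
        out[label] = CatalogModel(kappas=kappas, terms=terms, r2=r2)
    return out


# Node indices: 6 = exp[I2-3], 7 = [I2-3]^2, 8 = exp([I2-3]^2),
# 12 = exp([I4f*-1]^2), 19 = [I4n*-1]^2, 20 = exp([I4n*-1]^2),
# 21 = [I8fs], 23 = [I8fs]^2, 24 = exp([I8fs]^2).

SHEET_NORMAL_DISPERSION = _sweep(
    "sn",
    {
        "0": ({7: 5.153, 12: (21.062, 0.081), 20: (4.132, 0.340), 24: (0.511, 0.485)}, 0.890),
        "1/15": ({7: 5.108, 12: (23.844, 0.063), 20: (4.683, 0.380), 23: 0.257}, 0.898),
        "2/15": ({8: (1.075, 4.520), 12: (23.331, 0.065), 20: (3.565, 0.705), 24: (0.517, 0.532)}, 0.905),
        "1/5": ({7: 5.144, 12: (23.925, 0.059), 20: (2.598, 1.358), 24: (0.537, 0.514)}, 0.914),
        "4/15": ({8: (1.215, 3.813), 12: (24.687, 0.055), 20: (2.759, 2.228), 24: (0.605, 0.607)}, 0.922),
        "1/3": ({8: (1.401, 2.572), 12: (24.214, 0.055), 20: (4.044, 4.202), 24: (1.696, 0.351)}, 0.920),
    },
)

FIBER_DISPERSION = _sweep(
    "f",
    {
        "0": ({7: 5.153, 12: (21.062, 0.081), 20: (4.132, 0.340), 24: (0.511, 0.485)}, 0.890),
        "1/15": ({7: 5.121, 12: (25.558, 0.105), 20: (5.517, 0.214), 23: 0.222}, 0.905),
        "2/15": ({7: 5.290, 12: (24.893, 0.199), 20: (5.644, 0.161), 21: 0.104}, 0.904),
        "1/5": ({7: 5.527, 12: (23.176, 0.406), 19: 0.608, 21: 0.035}, 0.885),
        "4/15": ({7: 5.308, 12: (14.619, 1.438)}, 0.852),
        "1/3": ({6: (0.629, 0.721), 7: 3.080, 12: (5.059, 9.141)}, 0.720),
    },
)

EQUAL_DISPERSION = _sweep(
    "fsn",
    {
        "0": ({7: 5.153, 12: (21.062, 0.081), 20: (4.132, 0.340), 24: (0.511, 0.485)}, 0.890),
        "1/15": ({8: (1.112, 4.333), 12: (25.315, 0.105), 20: (5.532, 0.286), 23: 0.270}, 0.910),
        "2/15": ({8: (1.222, 4.179), 12: (25.442, 0.187), 19: 1.755}, 0.904),
        "1/5": ({7: 5.579, 12: (24.149, 0.370), 20: (1.393, 1.030)}, 0.888),
        "4/15": ({7: 5.303, 12: (14.439, 1.459)}, 0.854),
        "1/3": ({6: (0.642, 0.740), 7: 3.026, 12: (5.359, 8.582)}, 0.722),
    },
)

_SWEEPS = {
    "sheet_normal": SHEET_NORMAL_DISPERSION,
    "fiber": FIBER_DISPERSION,
    "equal": EQUAL_DISPERSION,
}


def get_model(sweep: str, level: str) -> CatalogModel:
    """Look up a catalog model, e.g. get_model('equal', '1/15')."""
    try:
        return _SWEEPS[sweep][level]
    except KeyError:
        raise KeyError(
            f"unknown catalog entry ({sweep!r}, {level!r}); sweeps: {sorted(_SWEEPS)}, "
            f"levels: {KAPPA_LEVELS}"
        ) from None
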