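"""Loading protocols, synthetic datasets, noise injection, I/O, and reporting.

The experimental campaign emulated here consists of eleven protocols on the
same cube of myocardial tissue: six triaxial simple-shear tests (one per
mode fs, fn, sf, sn, nf, ns, each reporting the shear stress sigma_ij) and
five biaxial extension tests at stretch-increment ratios 1:1, 1:0.5,
1:0.75, 0.5:1, 0.75:1 between the fiber and normal directions (each
reporting sigma_ff and sigma_nn under plane stress through the sheet
thickness).  Ratios scale the stretch *increments* (lambda - 1), so all
protocol stretches stay >= 1.

A dataset is a tidy table of scalar stress samples, one row per
(protocol, grid point, stress channel).  Synthetic datasets are produced by
forward-simulating any weight set; measurement noise is modeled as additive
Gaussian perturbations scaled by each channel's stress standard deviation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import (
    ModelWeights,
    N_TERMS,
    INVARIANT_LABELS,
    node_term,
    term_label,
)
from .dispersion import DispersionParams
from .kinematics import SHEAR_MODES
from .stress import biaxial_stresses, shear_stress

__all__ = [
    "BIAXIAL_RATIOS",
    "NOISE_PRESETS",
    "Protocol",
    "NoiseSpec",
    "Dataset",
    "default_protocols",
    "simulate_dataset",
    "add_noise",
    "read_dataset",
    "write_dataset",
    "report_active_terms",
    "invariant_magnitudes",
]

#: Biaxial stretch-increment ratios (fiber : normal).
BIAXIAL_RATIOS = ("1:1", "1:0.5", "1:0.75", "0.5:1", "0.75:1")

#: Noise levels studied systematically (fraction of per-channel stress std).
NOISE_PRESETS = (0.03, 0.05, 0.07, 0.1)

_COLUMNS = ["protocol", "mode_or_ratio", "strain_or_stretch_f", "stretch_n", "channel", "stress_kPa"]


@dataclass(frozen=True)
class Protocol:
    """One loading protocol: a shear mode with a gamma grid, or a biaxial ratio
    with fiber/normal stretch grids."""

    kind: str  # "shear" | "biaxial"
    label: str  # shear mode or ratio string
    grid_f: np.ndarray  # gamma (shear) or lambda_f (biaxial)
    grid_n: np.ndarray | None = None  # lambda_n (biaxial only)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_f, float)
        object.__setattr__(self, "grid_f", g)
        if self.kind == "shear":
            if self.label not in SHEAR_MODES:
                raise ValueError(f"unknown shear mode {self.label!r}")
            start = 0.0
        elif self.kind == "biaxial":
            if self.label not in BIAXIAL_RATIOS:
                raise ValueError(f"unknown biaxial ratio {self.label!r}")
            gn = np.asarray(self.grid_n, float)
            object.__setattr__(self, "grid_n", gn)
            if gn.shape != g.shape:
                raise ValueError("biaxial grids must have equal length")
            if not np.isclose(gn[0], 1.0) or np.any(np.diff(gn) < 0):
                raise ValueError("lambda_n grid must start at 1 and be non-decreasing")
            start = 1.0
        else:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not np.isclose(g[0], start) or np.any(np.diff(g) < 0):
            raise ValueError(f"{self.kind} grid must start at {start} and be non-decreasing")

    @property
    def name(self) -> str:
        return f"{self.kind}-{self.label}"

    @property
    def channels(self) -> tuple[str, ...]:
        if self.kind == "shear":
            return (f"sigma_{self.label}",)
        return ("sigma_ff", "sigma_nn")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian stress noise: value += k * N(0, std_channel)."""

    k: float
    seed: int = 0
    std_sigma: dict[tuple[str, str], float] | None = None  # per (protocol, channel) override

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("noise level k must be non-negative")


@dataclass
class Dataset:
    """Tidy stress dataset; one row per scalar stress sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {', '.join(missing)}")
        if len(self.table) == 0:
            raise ValueError("dataset is empty")
        self.table = self.table[_COLUMNS].reset_index(drop=True)

    @property
    def n_data(self) -> int:
        return len(self.table)

    @property
    def stresses(self) -> np.ndarray:
        return self.table["stress_kPa"].to_numpy()

    def channel_groups(self):
        """Iterate ((protocol, channel), row-index array) pairs."""
        return self.table.groupby(["protocol", "channel"], sort=False).indices.items()

    def channel_std(self) -> dict[tuple[str, str], float]:
        """Population std of the stress values per (protocol, channel)."""
        return {
            key: float(np.std(self.table["stress_kPa"].to_numpy()[idx]))
            for key, idx in self.channel_groups()
        }


def default_protocols(
    gamma_max: float = 0.5, lambda_max: float = 1.1, n_points: int = 17
) -> list[Protocol]:
    """The eleven standard protocols: six shear modes plus five biaxial ratios.

    Shear grids span gamma in [0, gamma_max]; for ratio r:q the stretches are
    lambda_f = 1 + r*t*(lambda_max - 1), lambda_n = 1 + q*t*(lambda_max - 1)
    with t in [0, 1] on n_points.
    """
    if gamma_max <= 0 or lambda_max <= 1:
        raise ValueError("need gamma_max > 0 and lambda_max > 1")
    protos = [
        Protocol("shear", mode, np.linspace(0.0, gamma_max, n_points)) for mode in SHEAR_MODES
    ]
    t = np.linspace(0.0, 1.0, n_points)
    for ratio in BIAXIAL_RATIOS:
        r, q = (float(v) for v in ratio.split(":"))
        protos.append(
            Protocol(
                "biaxial",
                ratio,
                1.0 + r * t * (lambda_max - 1.0),
                1.0 + q * t * (lambda_max - 1.0),
            )
        )
    return protos


def simulate_dataset(
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    protocols: list[Protocol] | None = None,
    form: str = "exact",
) -> Dataset:
    """Forward-simulate all protocol stress channels from a weight set."""
    kappas = kappas or DispersionParams()
    protocols = protocols if protocols is not None else default_protocols()
    rows = []
    for proto in protocols:
        if proto.kind == "shear":
            sig = np.asarray(shear_stress(proto.label, proto.grid_f, weights, kappas, form=form))
            for g, s in zip(proto.grid_f, sig):
                rows.append((proto.name, proto.label, g, 1.0, proto.channels[0], s))
        else:
            s_ff, s_nn = biaxial_stresses(proto.grid_f, proto.grid_n, weights, kappas, form=form)
            for lf, ln, sf, sn in zip(proto.grid_f, proto.grid_n, s_ff, s_nn):
                rows.append((proto.name, proto.label, lf, ln, "sigma_ff", sf))
                rows.append((proto.name, proto.label, lf, ln, "sigma_nn", sn))
    return Dataset(pd.DataFrame(rows, columns=_COLUMNS))


def add_noise(dataset: Dataset, spec: NoiseSpec) -> Dataset:
    """Perturb each stress sample once by k * N(0, std of its channel).

    The perturbation is drawn per sample and is reproducible for a fixed
    seed; k = 0 returns an identical copy.
    """
    table = dataset.table.copy()
    if spec.k == 0.0:
        return Dataset(table)
    rng = np.random.default_rng(spec.seed)
    stds = dict(spec.std_sigma) if spec.std_sigma else dataset.channel_std()
    values = table["stress_kPa"].to_numpy(copy=True)
    for key, idx in dataset.channel_groups():
        values[idx] += spec.k * rng.normal(0.0, stds[key], size=len(idx))
    table["stress_kPa"] = values
    return Dataset(table)


def write_dataset(dataset: Dataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def read_dataset(path) -> Dataset:
    """Read a dataset CSV, reporting the offending column or line on failure."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} missing column(s): {', '.join(missing)}")
    for col in ("strain_or_stretch_f", "stretch_n", "stress_kPa"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"dataset file {path}: malformed {col!r} on line {bad[0] + 2}")
        df[col] = coerced
    return Dataset(df)


# ---------------------------------------------------------------------------
# reporting


def _single_term_weights(weights: ModelWeights, j: int) -> ModelWeights:
    w = ModelWeights()
    w.set_node(j, *weights.node_weights(j))
    return w


def _term_magnitude(weights: ModelWeights, j: int) -> float:
    vals = weights.node_weights(j)
    return float(np.prod(vals))


def report_active_terms(
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    protocols: list[Protocol] | None = None,
    r2_mean: float | None = None,
    threshold: float = 0.005,
    form: str = "exact",
) -> pd.DataFrame:
    """Table of active energy terms in the printed-table layout.

    A term is *active* when its peak absolute stress contribution across the
    training protocols exceeds ``threshold`` (0.5% by default) of the peak
    total stress.  Columns: node index, weight labels, term expression,
    invariant, the weight value(s), and the combined magnitude in kPa (the
    product for an (inner, outer) pair, the value itself for a collapsed
    weight).  The mean R-squared, when supplied, is attached as a dataframe
    attribute ``r2_mean``.
    """
    kappas = kappas or DispersionParams()
    protocols = protocols if protocols is not None else default_protocols()
    total = simulate_dataset(weights, kappas, protocols, form=form)
    peak_total = float(np.max(np.abs(total.stresses)))
    rows = []
    for j in range(1, N_TERMS + 1):
        vals = weights.node_weights(j)
        if all(v == 0.0 for v in vals):
            continue
        contrib = simulate_dataset(_single_term_weights(weights, j), kappas, protocols, form=form)
        peak = float(np.max(np.abs(contrib.stresses)))
        if peak_total > 0 and peak < threshold * peak_total:
            continue
        row_k, power, activation = node_term(j)
        labels = (
            f"w1,{j}*w2,{j}" if activation == "identity" else f"w1,{j}, w2,{j}"
        )
        rows.append(
            {
                "node": j,
                "weights": labels,
                "term": term_label(j),
                "invariant": INVARIANT_LABELS[row_k],
                "w1": vals[0] if len(vals) == 2 else np.nan,
                "w2": vals[1] if len(vals) == 2 else np.nan,
                "magnitude_kPa": _term_magnitude(weights, j),
                "peak_stress_kPa": peak,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "node", "weights", "term", "invariant", "w1", "w2", "magnitude_kPa", "peak_stress_kPa",
        ],
    )
    report.attrs["r2_mean"] = r2_mean
    return report


def invariant_magnitudes(report: pd.DataFrame) -> dict[str, float]:
    """Sum of active-term magnitudes [kPa] per invariant, from a report table."""
    if len(report) == 0:
        return {}
    return report.groupby("invariant")["magnitude_kPa"].sum().to_dict()


def format_report(report: pd.DataFrame) -> str:
    """Pretty-printed report, with the mean R-squared footer when available."""
    buf = io.StringIO()
    if len(report) == 0:
        buf.write("(no active terms)\n")
    else:
        buf.write(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        buf.write("\n")
    r2 = report.attrs.get("r2_mean")
    if r2 is not None:
        buf.write(f"mean R^2 = {r2:.3f}\n")
    return buf.getvalue()


__all__.append("format_report")
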