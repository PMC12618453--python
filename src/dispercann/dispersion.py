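"""Axisymmetric fiber dispersion via generalized structure tensors.

Each structural direction (fiber, sheet, normal) is treated not as a single
vector but as a family of directions spread around the mean with a
pi-periodic von Mises orientation density of concentration ``b``.  The
second moment of that density is the generalized structure tensor

    H = kappa * I + (1 - 3*kappa) * dir (x) dir,

where the scalar dispersion parameter ``kappa in [0, 1/3]`` condenses the
spread: kappa = 0 is perfect alignment, kappa = 1/3 an isotropic cloud.
The dispersed squared-stretch invariants are the contractions C : H, which
reduce to the affine combinations

    I4i* = kappa_i * I1 + (1 - 3*kappa_i) * I4i.

``kappa`` is the primary parameter of the public API; the concentration
``b`` is an auxiliary parameterization connected through an integral of the
von Mises density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import dawsn

from .kinematics import InvariantSet

__all__ = [
    "DispersionParams",
    "von_mises_density",
    "kappa_from_b",
    "structure_tensor",
    "disperse_invariants",
    "kappa_table",
]


@dataclass(frozen=True)
class DispersionParams:
    """Dispersion parameters for the fiber, sheet, and normal families."""

    kappa_f: float = 0.0
    kappa_s: float = 0.0
    kappa_n: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kappa_f", "kappa_s", "kappa_n"):
            k = getattr(self, name)
            if not 0.0 <= k <= 1.0 / 3.0 + 1e-12:
                raise ValueError(f"{name} = {k} outside [0, 1/3]")

    def as_array(self) -> np.ndarray:
        return np.array([self.kappa_f, self.kappa_s, self.kappa_n])

    def kappa(self, label: str) -> float:
        return {"f": self.kappa_f, "s": self.kappa_s, "n": self.kappa_n}[label]


def von_mises_density(theta, b: float):
    """Pi-periodic von Mises density rho(theta) on the polar angle.

    rho(theta) = 4 sqrt(b / 2 pi) exp(b [cos 2 theta + 1]) / erfi(sqrt(2 b)),
    normalized so that the average of rho over the unit sphere is one:
    (1/4 pi) int rho domega = 1.  (The +1 in the exponent is required by that
    normalization; a variant without it integrates to exp(-b).)

    Evaluated through the Dawson function, erfi(x) e^{-x^2} = 2 D(x)/sqrt(pi),
    so the exponent b (cos 2 theta - 1) <= 0 never overflows even for
    concentrations of order 1e3.
    """
    if b <= 0.0:
        raise ValueError(f"concentration b = {b} must be positive")
    theta = np.asarray(theta, dtype=float)
    # erfi(sqrt(2b)) = exp(2b) * 2*D(sqrt(2b))/sqrt(pi)
    scaled_erfi = 2.0 * dawsn(np.sqrt(2.0 * b)) / np.sqrt(np.pi)
    out = 4.0 * np.sqrt(b / (2.0 * np.pi)) * np.exp(b * (np.cos(2.0 * theta) - 1.0)) / scaled_erfi
    return out if out.ndim else float(out)


def kappa_from_b(b: float, *, tol: float = 1e-10) -> float:
    """Dispersion parameter kappa = 1/4 * int_0^pi rho(theta) sin^3(theta) dtheta.

    Adaptive quadrature; the result falls in (0, 1/3) without clamping,
    approaching 1/3 as b -> 0 (isotropy) and 0 as b -> infinity (alignment).
    """
    if b <= 0.0:
        raise ValueError(f"concentration b = {b} must be positive")
    val, err = integrate.quad(
        lambda t: von_mises_density(t, b) * np.sin(t) ** 3,
        0.0,
        np.pi,
        epsabs=tol,
        epsrel=tol,
        limit=200,
    )
    if err > 1e-6:
        raise ArithmeticError(f"kappa(b={b}) quadrature did not converge (err={err})")
    return 0.25 * val


def structure_tensor(kappa: float, direction: np.ndarray) -> np.ndarray:
    """H = kappa * I + (1 - 3 kappa) * dir (x) dir; trace(H) = 1."""
    if not 0.0 <= kappa <= 1.0 / 3.0 + 1e-12:
        raise ValueError(f"kappa = {kappa} outside [0, 1/3]")
    d = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-10):
        raise ValueError("direction must be a unit vector")
    return kappa * np.eye(3) + (1.0 - 3.0 * kappa) * np.outer(d, d)


def disperse_invariants(
    inv: InvariantSet, kappas: DispersionParams
) -> tuple[float, float, float]:
    """Dispersed invariants (I4f*, I4s*, I4n*) = kappa_i I1 + (1 - 3 kappa_i) I4i."""
    return (
        kappas.kappa_f * inv.I1 + (1.0 - 3.0 * kappas.kappa_f) * inv.I4f,
        kappas.kappa_s * inv.I1 + (1.0 - 3.0 * kappas.kappa_s) * inv.I4s,
        kappas.kappa_n * inv.I1 + (1.0 - 3.0 * kappas.kappa_n) * inv.I4n,
    )


def kappa_table(b_min: float, b_max: float, n: int) -> np.ndarray:
    """(b, kappa) pairs on a log-spaced concentration grid, as an (n, 2) array."""
    if b_min <= 0 or b_max <= b_min or n < 2:
        raise ValueError("need 0 < b_min < b_max and n >= 2")
    bs = np.logspace(np.log10(b_min), np.log10(b_max), n)
    return np.column_stack([bs, [kappa_from_b(b) for b in bs]])
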