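"""Cauchy stresses for the incompressible orthotropic energy.

The general stress follows from the chain rule over the eight network-input
invariants,

    sigma = sum_k dpsi/dI_k * (dI_k/dF) . F^T  -  p I,

with the invariant push-forwards evaluated analytically (dispersed fourth
invariants push forward as 2 F H_i F^T).  The hydrostatic pressure p is the
incompressibility Lagrange multiplier; for the biaxial plane-stress protocol
it is fixed by requiring the through-thickness stress sigma_ss = 0, for
shear it never enters the off-diagonal components used in training.

Every protocol stress is a *linear* functional of the eight energy
derivatives with deformation-dependent coefficients; the closed forms below
expose those coefficients, which the trainer also reuses for its analytic
weight gradients.

Two variants of the closed forms exist.  ``form="exact"`` (default) is the
algebraically exact reduction of the general formula, verified against a
finite-difference oracle.  ``form="printed"`` reproduces a commonly printed
truncation in which the plane-stress pressure omits the anisotropic
contributions and the shear coupling term carries an extra factor gamma; it
is provided only for comparison studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import ModelWeights, corrected_bases, energy_gradients
from .dispersion import DispersionParams, structure_tensor
from .kinematics import (
    MaterialFrame,
    DeformationGradient,
    ShearState,
    biaxial_deformation_gradient,
    compute_invariants,
    shear_deformation_gradient,
)

__all__ = [
    "StressState",
    "cauchy_stress_general",
    "plane_stress_pressure",
    "shear_stress",
    "biaxial_stresses",
    "shear_coefficients",
    "biaxial_coefficients",
]

_AXIS = {"f": 0, "s": 1, "n": 2}
_I8_ROW = {frozenset("fs"): 5, frozenset("fn"): 6, frozenset("sn"): 7}


@dataclass(frozen=True)
class StressState:
    """Symmetric Cauchy stress [kPa] and the hydrostatic pressure that built it."""

    sigma: np.ndarray
    p: float


def _invariant_pushforwards(
    F: np.ndarray, frame: MaterialFrame, kappas: DispersionParams
) -> np.ndarray:
    """The eight tensors (dI_k/dF).F^T, shape (8, 3, 3)."""
    B = F @ F.T
    I1 = np.trace(B)
    out = np.empty((8, 3, 3))
    out[0] = 2.0 * B
    out[1] = 2.0 * (I1 * B - B @ B)
    for row, label in ((2, "f"), (3, "s"), (4, "n")):
        H = structure_tensor(kappas.kappa(label), frame.direction(label))
        out[row] = 2.0 * F @ H @ F.T
    for row, (a, b) in ((5, "fs"), (6, "fn"), (7, "sn")):
        va = F @ frame.direction(a)
        vb = F @ frame.direction(b)
        out[row] = np.outer(va, vb) + np.outer(vb, va)
    return out


def cauchy_stress_general(
    F: DeformationGradient | np.ndarray,
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    frame: MaterialFrame | None = None,
    p: float = 0.0,
) -> StressState:
    """General incompressible Cauchy stress at a given hydrostatic pressure."""
    frame = frame or MaterialFrame()
    kappas = kappas or DispersionParams()
    if not isinstance(F, DeformationGradient):
        F = DeformationGradient(F)
    inv = compute_invariants(F, frame)
    x, mask = corrected_bases(inv, kappas)
    g = energy_gradients(x, weights, mask)
    push = _invariant_pushforwards(F.F, frame, kappas)
    sigma = np.tensordot(g, push, axes=1) - p * np.eye(3)
    return StressState(sigma=sigma, p=p)


def plane_stress_pressure(
    F: DeformationGradient | np.ndarray,
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    frame: MaterialFrame | None = None,
    direction: str = "s",
) -> float:
    """Pressure that annihilates the normal stress along a structural direction.

    Solving sigma_dd = 0 in the general formula gives p as the dd-component
    of the deviatoric part, including the anisotropic (dispersed) terms.
    """
    state = cauchy_stress_general(F, weights, kappas, frame, p=0.0)
    frame = frame or MaterialFrame()
    d = frame.direction(direction)
    return float(d @ state.sigma @ d)


def shear_coefficients(
    mode: str,
    gamma: np.ndarray | float,
    kappas: DispersionParams | tuple[float, float, float],
    form: str = "exact",
) -> np.ndarray:
    """Coefficients c (..., 8) with sigma_ij = sum_k c_k * dpsi/dI_k for shear mode ij.

    Exact form (from the general stress):

        sigma_ij = 2 gamma [d1 + d2 + (1-2 kappa_i) d4i + kappa_j d4j
                            + kappa_k d4k] + d8ij,

    with k the out-of-plane direction.  The printed variant drops the
    kappa_k term and uses gamma * d8ij for the coupling contribution.
    """
    if isinstance(kappas, DispersionParams):
        kf, ks, kn = kappas.kappa_f, kappas.kappa_s, kappas.kappa_n
    else:
        kf, ks, kn = kappas
    kmap = {"f": kf, "s": ks, "n": kn}
    i, j = ShearState(mode, 0.0).mode
    (k,) = set("fsn") - {i, j}
    g = np.asarray(gamma, float)
    c = np.zeros(g.shape + (8,))
    tg = 2.0 * g
    c[..., 0] = tg
    c[..., 1] = tg
    c[..., 2 + _AXIS[i]] = tg * (1.0 - 2.0 * kmap[i])
    c[..., 2 + _AXIS[j]] = tg * kmap[j]
    i8 = _I8_ROW[frozenset(mode)]
    if form == "exact":
        c[..., 2 + _AXIS[k]] = tg * kmap[k]
        c[..., i8] = 1.0
    elif form == "printed":
        c[..., i8] = g
    else:
        raise ValueError(f"unknown form {form!r}; expected 'exact' or 'printed'")
    return c


def biaxial_coefficients(
    lambda_f: np.ndarray | float,
    lambda_n: np.ndarray | float,
    kappas: DispersionParams | tuple[float, float, float],
    form: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient vectors (c_ff, c_nn), each (..., 8), for plane-stress biaxial extension.

    Exact form: the pressure is solved from the full sigma_ss = 0 condition
    of the general stress, including the dispersed anisotropic terms,

        sigma_ff = 2 (lf^2 - ls^2) d1 + 2 (lf^2 - ls^2) ln^2 d2
                   + 2 [lf^2 (1-2 kf) - ls^2 kf] d4f
                   + 2 [lf^2 ks - ls^2 (1-2 ks)] d4s
                   + 2 kn (lf^2 - ls^2) d4n,

    and symmetrically (f <-> n) for sigma_nn.  The printed variant keeps the
    isotropic part but truncates the pressure's anisotropic terms.
    """
    if isinstance(kappas, DispersionParams):
        kf, ks, kn = kappas.kappa_f, kappas.kappa_s, kappas.kappa_n
    else:
        kf, ks, kn = kappas
    lf = np.asarray(lambda_f, float)
    ln = np.asarray(lambda_n, float)
    ls = 1.0 / (lf * ln)
    af, as_, an = lf**2, ls**2, ln**2

    c_ff = np.zeros(af.shape + (8,))
    c_nn = np.zeros(af.shape + (8,))
    c_ff[..., 0] = 2.0 * (af - as_)
    c_nn[..., 0] = 2.0 * (an - as_)
    c_ff[..., 1] = 2.0 * (af - as_) * an
    if form == "exact":
        c_nn[..., 1] = 2.0 * (an - as_) * af
        c_ff[..., 2] = 2.0 * (af * (1.0 - 2.0 * kf) - as_ * kf)
        c_ff[..., 3] = 2.0 * (af * ks - as_ * (1.0 - 2.0 * ks))
        c_ff[..., 4] = 2.0 * kn * (af - as_)
        c_nn[..., 2] = 2.0 * kf * (an - as_)
        c_nn[..., 3] = 2.0 * (an * ks - as_ * (1.0 - 2.0 * ks))
        c_nn[..., 4] = 2.0 * (an * (1.0 - 2.0 * kn) - as_ * kn)
    elif form == "printed":
        c_nn[..., 1] = 2.0 * (an - as_) * an
        c_ff[..., 2] = 2.0 * af * (1.0 - 2.0 * kf)
        c_ff[..., 4] = 2.0 * af * kn
        c_nn[..., 2] = 2.0 * an * kf
        c_nn[..., 4] = 2.0 * an * (1.0 - 2.0 * kn)
    else:
        raise ValueError(f"unknown form {form!r}; expected 'exact' or 'printed'")
    return c_ff, c_nn


def _gradients_for(
    F: DeformationGradient, weights: ModelWeights, kappas: DispersionParams, frame: MaterialFrame
) -> np.ndarray:
    inv = compute_invariants(F, frame)
    x, mask = corrected_bases(inv, kappas)
    return energy_gradients(x, weights, mask)


def shear_stress(
    mode: str,
    gamma: np.ndarray | float,
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    frame: MaterialFrame | None = None,
    form: str = "exact",
) -> np.ndarray | float:
    """Shear stress sigma_ij(gamma) [kPa] for one of the six triaxial modes."""
    kappas = kappas or DispersionParams()
    frame = frame or MaterialFrame()
    gam = np.atleast_1d(np.asarray(gamma, float))
    coeff = shear_coefficients(mode, gam, kappas, form=form)
    out = np.empty(gam.shape)
    for idx, g in enumerate(gam):
        F = shear_deformation_gradient(ShearState(mode, float(g)), frame)
        out[idx] = coeff[idx] @ _gradients_for(F, weights, kappas, frame)
    return out if np.ndim(gamma) else float(out[0])


def biaxial_stresses(
    lambda_f: np.ndarray | float,
    lambda_n: np.ndarray | float,
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    frame: MaterialFrame | None = None,
    form: str = "exact",
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Plane-stress biaxial normal stresses (sigma_ff, sigma_nn) [kPa]."""
    kappas = kappas or DispersionParams()
    frame = frame or MaterialFrame()
    lf = np.atleast_1d(np.asarray(lambda_f, float))
    ln = np.atleast_1d(np.asarray(lambda_n, float))
    lf, ln = np.broadcast_arrays(lf, ln)
    c_ff, c_nn = biaxial_coefficients(lf, ln, kappas, form=form)
    s_ff = np.empty(lf.shape)
    s_nn = np.empty(lf.shape)
    for idx in range(lf.size):
        F = biaxial_deformation_gradient(float(lf.flat[idx]), float(ln.flat[idx]), frame)
        g = _gradients_for(F, weights, kappas, frame)
        s_ff.flat[idx] = c_ff.reshape(-1, 8)[idx] @ g
        s_nn.flat[idx] = c_nn.reshape(-1, 8)[idx] @ g
    if np.ndim(lambda_f) or np.ndim(lambda_n):
        return s_ff, s_nn
    return float(s_ff.flat[0]), float(s_nn.flat[0])
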