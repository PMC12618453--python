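"""Homogeneous deformations for triaxial-shear and biaxial-extension tests.

Myocardium is treated as a perfectly incompressible orthotropic solid with
three orthonormal mean structural directions: fiber ``f0`` (myocyte axis),
sheet ``s0`` (laminar sheet), and normal ``n0`` (sheet normal).  All test
protocols are homogeneous, so a single deformation gradient ``F`` with
``det F = 1`` describes each load step, and the mechanical state is fully
captured by nine invariants of the right Cauchy-Green tensor ``C = F^T F``:
the isotropic ``I1, I2, I3``, the squared stretches ``I4f, I4s, I4n`` along
the structural directions, and the coupling invariants ``I8fs, I8fn, I8sn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SHEAR_MODES",
    "MaterialFrame",
    "DeformationGradient",
    "InvariantSet",
    "ShearState",
    "BiaxialState",
    "shear_deformation_gradient",
    "biaxial_deformation_gradient",
    "compute_invariants",
]

#: The six triaxial shear modes.  Mode ``ij`` shears the ij-plane along the
#: j-direction: material lines along i are tilted (and stretched) toward j.
SHEAR_MODES = ("fs", "fn", "sf", "sn", "nf", "ns")

_AXIS = {"f": 0, "s": 1, "n": 2}


@dataclass(frozen=True)
class MaterialFrame:
    """Orthonormal fiber/sheet/normal reference directions.

    Defaults to the Cartesian basis (f0 = e_x, s0 = e_y, n0 = e_z).
    """

    f0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    s0: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    n0: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        Q = self.as_matrix()
        if not np.allclose(Q.T @ Q, np.eye(3), atol=1e-12):
            raise ValueError("material frame must be orthonormal to 1e-12")

    def as_matrix(self) -> np.ndarray:
        """Columns are (f0, s0, n0)."""
        return np.column_stack(
            [np.asarray(self.f0, float), np.asarray(self.s0, float), np.asarray(self.n0, float)]
        )

    def direction(self, label: str) -> np.ndarray:
        return (self.f0, self.s0, self.n0)[_AXIS[label]]


@dataclass(frozen=True)
class DeformationGradient:
    """A deformation gradient and its determinant (J = 1 for all protocols)."""

    F: np.ndarray
    J: float = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        object.__setattr__(self, "F", F)
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError(f"det F = {J} must be positive")
        object.__setattr__(self, "J", J)

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor F^T F."""
        return self.F.T @ self.F


@dataclass(frozen=True)
class InvariantSet:
    I1: float
    I2: float
    I3: float
    I4f: float
    I4s: float
    I4n: float
    I8fs: float
    I8fn: float
    I8sn: float

    def I4(self, label: str) -> float:
        return (self.I4f, self.I4s, self.I4n)[_AXIS[label]]

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.I1, self.I2, self.I3,
            self.I4f, self.I4s, self.I4n,
            self.I8fs, self.I8fn, self.I8sn,
        )


@dataclass(frozen=True)
class ShearState:
    """Simple shear of amount gamma in one of the six ij modes."""

    mode: str
    gamma: float

    def __post_init__(self) -> None:
        if self.mode not in SHEAR_MODES:
            raise ValueError(f"unknown shear mode {self.mode!r}; expected one of {SHEAR_MODES}")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")


@dataclass(frozen=True)
class BiaxialState:
    """Biaxial extension along f and n; the sheet stretch follows from J = 1."""

    lambda_f: float
    lambda_n: float

    def __post_init__(self) -> None:
        if self.lambda_f <= 0 or self.lambda_n <= 0:
            raise ValueError("stretches must be positive")

    @property
    def lambda_s(self) -> float:
        return 1.0 / (self.lambda_f * self.lambda_n)


def shear_deformation_gradient(
    state: ShearState, frame: MaterialFrame | None = None
) -> DeformationGradient:
    """F = I + gamma * (e_j x e_i) for mode ij.

    The displacement is along j and varies with the i coordinate, so material
    lines along i are stretched: I4i = 1 + gamma^2.  det F = 1 exactly.
    """
    frame = frame or MaterialFrame()
    i, j = state.mode
    e_i = np.asarray(frame.direction(i), float)
    e_j = np.asarray(frame.direction(j), float)
    F = np.eye(3) + state.gamma * np.outer(e_j, e_i)
    return DeformationGradient(F)


def biaxial_deformation_gradient(
    lambda_f: float, lambda_n: float, frame: MaterialFrame | None = None
) -> DeformationGradient:
    """Diagonal stretch (lambda_f, 1/(lambda_f*lambda_n), lambda_n) in the frame axes."""
    state = BiaxialState(lambda_f, lambda_n)
    frame = frame or MaterialFrame()
    Q = frame.as_matrix()
    D = np.diag([state.lambda_f, state.lambda_s, state.lambda_n])
    return DeformationGradient(Q @ D @ Q.T)


def compute_invariants(
    F: DeformationGradient | np.ndarray, frame: MaterialFrame | None = None
) -> InvariantSet:
    """The nine invariants of C = F^T F in the given material frame."""
    frame = frame or MaterialFrame()
    if not isinstance(F, DeformationGradient):
        F = DeformationGradient(F)
    C = F.C
    f0, s0, n0 = frame.f0, frame.s0, frame.n0
    I1 = float(np.trace(C))
    I2 = 0.5 * (I1 * I1 - float(np.sum(C * C)))
    I3 = float(np.linalg.det(C))
    return InvariantSet(
        I1=I1,
        I2=I2,
        I3=I3,
        I4f=float(f0 @ C @ f0),
        I4s=float(s0 @ C @ s0),
        I4n=float(n0 @ C @ n0),
        I8fs=float(f0 @ C @ s0),
        I8fn=float(f0 @ C @ n0),
        I8sn=float(s0 @ C @ n0),
    )
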