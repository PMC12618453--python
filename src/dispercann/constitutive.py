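"""The 32-term orthotropic free energy, its derivatives, and the tension switch.

The energy is a constitutive neural network in disguise: a fixed library of
32 algebraic terms built from eight input invariants

    I1-3, I2-3, I4f*-1, I4s*-1, I4n*-1, I8fs, I8fn, I8sn

(the corrections make the energy vanish at F = I).  Each invariant row
contributes four nodes: the first and second powers of the corrected
invariant, each passed through either the identity or the exponential
``w2*[exp(w1*base) - 1]``.  For identity nodes the two layer weights only
ever appear as a product, so they are collapsed into a single effective
weight; this reduces the trainable parameters from 64 to 48, all constrained
non-negative.  Inner (first-layer) weights are unitless; outer weights carry
units of kPa, so the energy and all stresses are in kPa.

Directional I4* rows are gated by a tension-compression switch: they
contribute only while the *undispersed* squared stretch I4i >= 1, which
prevents non-physiological compressive stiffening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dispersion import DispersionParams, disperse_invariants
from .kinematics import InvariantSet

__all__ = [
    "INVARIANT_LABELS",
    "N_TERMS",
    "N_WEIGHTS",
    "ModelWeights",
    "SwitchFlags",
    "node_term",
    "term_label",
    "tension_switch",
    "corrected_bases",
    "free_energy",
    "energy_gradients",
    "save_model",
    "load_model",
]

#: Network-input invariants in row order; row k owns nodes 4k+1 .. 4k+4.
INVARIANT_LABELS = ("I1", "I2", "I4f*", "I4s*", "I4n*", "I8fs", "I8fn", "I8sn")
N_TERMS = 32
N_WEIGHTS = 48

#: Hard cap on the exponential inner argument; beyond this the model is
#: numerically meaningless and silently clipping would corrupt gradients.
EXP_GUARD = 50.0

_BASE_LABEL = ("[I1-3]", "[I2-3]", "[I4f*-1]", "[I4s*-1]", "[I4n*-1]", "[I8fs]", "[I8fn]", "[I8sn]")


def node_term(j: int) -> tuple[int, int, str]:
    """Map node index j in 1..32 to (invariant row, power, activation)."""
    if not 1 <= j <= N_TERMS:
        raise ValueError(f"node index {j} outside 1..32")
    row, slot = divmod(j - 1, 4)
    power = 1 if slot < 2 else 2
    activation = "identity" if slot % 2 == 0 else "exp"
    return row, power, activation


def term_label(j: int) -> str:
    """Human-readable form of node j, e.g. 'exp([I4f*-1]^2)'."""
    row, power, activation = node_term(j)
    base = _BASE_LABEL[row] + ("^2" if power == 2 else "")
    return f"exp({base})" if activation == "exp" else base


def _weight_keys(j: int) -> tuple[str, ...]:
    _, _, activation = node_term(j)
    if activation == "identity":
        return (f"w1,{j}*w2,{j}",)
    return (f"w1,{j}", f"w2,{j}")


@dataclass
class ModelWeights:
    """The 48 non-negative parameters of the 32-term energy.

    Stored per invariant row (8 rows):

    - ``lin1``: collapsed effective weight of the power-1 identity node [kPa]
    - ``exp1``: (inner, outer) pair of the power-1 exponential node [-, kPa]
    - ``lin2``: collapsed effective weight of the power-2 identity node [kPa]
    - ``exp2``: (inner, outer) pair of the power-2 exponential node [-, kPa]
    """

    lin1: np.ndarray = field(default_factory=lambda: np.zeros(8))
    exp1: np.ndarray = field(default_factory=lambda: np.zeros((8, 2)))
    lin2: np.ndarray = field(default_factory=lambda: np.zeros(8))
    exp2: np.ndarray = field(default_factory=lambda: np.zeros((8, 2)))

    def __post_init__(self) -> None:
        self.lin1 = np.asarray(self.lin1, float).reshape(8).copy()
        self.exp1 = np.asarray(self.exp1, float).reshape(8, 2).copy()
        self.lin2 = np.asarray(self.lin2, float).reshape(8).copy()
        self.exp2 = np.asarray(self.exp2, float).reshape(8, 2).copy()
        self.validate()

    def validate(self) -> None:
        for name in ("lin1", "exp1", "lin2", "exp2"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite weight in {name}")
            if np.any(a < 0):
                raise ValueError(f"negative weight in {name}: all 48 weights must be >= 0")

    # -- flat vector view used by the optimizer ------------------------------
    def to_vector(self) -> np.ndarray:
        """Flat (48,) vector: [lin1 | exp1_inner | exp1_outer | lin2 | exp2_inner | exp2_outer]."""
        return np.concatenate(
            [self.lin1, self.exp1[:, 0], self.exp1[:, 1], self.lin2, self.exp2[:, 0], self.exp2[:, 1]]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelWeights":
        v = np.asarray(v, float).reshape(48)
        return cls(
            lin1=v[0:8],
            exp1=np.column_stack([v[8:16], v[16:24]]),
            lin2=v[24:32],
            exp2=np.column_stack([v[32:40], v[40:48]]),
        )

    # -- node-indexed access -------------------------------------------------
    def node_weights(self, j: int) -> tuple[float, ...]:
        row, power, activation = node_term(j)
        if activation == "identity":
            arr = self.lin1 if power == 1 else self.lin2
            return (float(arr[row]),)
        arr = self.exp1 if power == 1 else self.exp2
        return (float(arr[row, 0]), float(arr[row, 1]))

    def set_node(self, j: int, *values: float) -> None:
        row, power, activation = node_term(j)
        if activation == "identity":
            (w,) = values
            (self.lin1 if power == 1 else self.lin2)[row] = w
        else:
            w1, w2 = values
            arr = self.exp1 if power == 1 else self.exp2
            arr[row] = (w1, w2)
        self.validate()

    @classmethod
    def from_terms(cls, terms: dict[int, float | tuple[float, float]]) -> "ModelWeights":
        """Build from a sparse {node index: weight or (inner, outer)} map."""
        w = cls()
        for j, val in terms.items():
            w.set_node(j, *(val if isinstance(val, (tuple, list)) else (val,)))
        return w

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for j in range(1, N_TERMS + 1):
            for key, val in zip(_weight_keys(j), self.node_weights(j)):
                out[key] = val
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelWeights":
        w = cls()
        for j in range(1, N_TERMS + 1):
            keys = _weight_keys(j)
            w.set_node(j, *(float(d.get(k, 0.0)) for k in keys))
        return w


@dataclass(frozen=True)
class SwitchFlags:
    """Tension flags for the f/s/n rows; flag i is true iff undispersed I4i >= 1."""

    active_f: bool
    active_s: bool
    active_n: bool

    def as_mask(self) -> np.ndarray:
        """(8,) multiplier over invariant rows; I8 and isotropic rows always on."""
        m = np.ones(8)
        m[2] = float(self.active_f)
        m[3] = float(self.active_s)
        m[4] = float(self.active_n)
        return m


def tension_switch(inv: InvariantSet) -> SwitchFlags:
    """Evaluate the tension-compression switch on the undispersed I4 values."""
    return SwitchFlags(inv.I4f >= 1.0, inv.I4s >= 1.0, inv.I4n >= 1.0)


def corrected_bases(
    inv: InvariantSet, kappas: DispersionParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected network inputs x (8,) and the switch mask (8,).

    x = (I1-3, I2-3, I4f*-1, I4s*-1, I4n*-1, I8fs, I8fn, I8sn) with the
    dispersed fourth invariants; the switch is evaluated on the raw I4i.
    """
    kappas = kappas or DispersionParams()
    i4f, i4s, i4n = disperse_invariants(inv, kappas)
    x = np.array(
        [inv.I1 - 3.0, inv.I2 - 3.0, i4f - 1.0, i4s - 1.0, i4n - 1.0, inv.I8fs, inv.I8fn, inv.I8sn]
    )
    return x, tension_switch(inv).as_mask()


def _guarded_exp(arg: np.ndarray, which: str) -> np.ndarray:
    if np.any(arg > EXP_GUARD):
        j = int(np.argmax(np.atleast_1d(arg)))
        raise OverflowError(
            f"exponential inner argument {np.max(arg):.3g} exceeds {EXP_GUARD} "
            f"in {which} row {j}: model or deformation out of range"
        )
    return np.exp(arg)


def free_energy(x: np.ndarray, weights: ModelWeights, mask: np.ndarray | None = None) -> float:
    """Free energy psi [kPa] from the corrected bases x (..., 8).

    ``mask`` is the (..., 8) tension-switch multiplier; masked rows contribute
    zero energy.  psi(x=0) = 0 exactly for any admissible weights.
    """
    x = np.asarray(x, float)
    m = np.ones_like(x) if mask is None else np.asarray(mask, float)
    xm = x * m
    e1 = _guarded_exp(weights.exp1[:, 0] * xm, "exp-linear")
    e2 = _guarded_exp(weights.exp2[:, 0] * xm**2, "exp-quadratic")
    psi = (
        weights.lin1 * xm
        + weights.exp1[:, 1] * (e1 - 1.0)
        + weights.lin2 * xm**2
        + weights.exp2[:, 1] * (e2 - 1.0)
    )
    return float(np.sum(psi, axis=-1)) if psi.ndim == 1 else np.sum(psi, axis=-1)


def energy_gradients(
    x: np.ndarray, weights: ModelWeights, mask: np.ndarray | None = None
) -> np.ndarray:
    """The eight partials dpsi/dI_k [kPa] at the corrected bases x (..., 8).

    Per row: w_lin1 + w1 w2 exp(w1 x) + 2 w_lin2 x + 2 w1 w2 x exp(w1 x^2),
    zeroed where the tension switch is off.
    """
    x = np.asarray(x, float)
    m = np.ones_like(x) if mask is None else np.asarray(mask, float)
    xm = x * m
    e1 = _guarded_exp(weights.exp1[:, 0] * xm, "exp-linear")
    e2 = _guarded_exp(weights.exp2[:, 0] * xm**2, "exp-quadratic")
    g = (
        weights.lin1
        + weights.exp1[:, 0] * weights.exp1[:, 1] * e1
        + 2.0 * weights.lin2 * xm
        + 2.0 * weights.exp2[:, 0] * weights.exp2[:, 1] * xm * e2
    )
    return g * m


def save_model(
    path: str | Path,
    weights: ModelWeights,
    kappas: DispersionParams | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a model JSON: named weight map, kappa triple, free-form metadata."""
    kappas = kappas or DispersionParams()
    doc = {
        "weights": weights.to_dict(),
        "kappas": {"f": kappas.kappa_f, "s": kappas.kappa_s, "n": kappas.kappa_n},
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> tuple[ModelWeights, DispersionParams, dict]:
    doc = json.loads(Path(path).read_text())
    weights = ModelWeights.from_dict(doc["weights"])
    k = doc.get("kappas", {})
    kappas = DispersionParams(k.get("f", 0.0), k.get("s", 0.0), k.get("n", 0.0))
    return weights, kappas, doc.get("metadata", {})
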