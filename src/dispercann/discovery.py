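"""Sparse model discovery: loss, initialization, Adam training, goodness of fit.

The discovery problem is an L1-regularized nonlinear least-squares fit of
the 48 non-negative energy weights (and optionally the three dispersion
parameters) to all protocol stress channels simultaneously:

    L(w) = sum_i (sigma_model_i - sigma_measured_i)^2 + alpha * sum |w|,

summing the squared stress misfit over all samples.  The L1 penalty drives
most of the 32 library terms to zero, leaving a sparse, interpretable
model.  Three data-term normalizations are supported via
``loss_normalization``: ``"sum"`` (default; the raw sum above, under which
published discovered models at alpha = 0.01 are reproduced), ``"per_channel"``
(mean within each stress channel, summed over channels, as a multi-output
trainer would compute -- stronger effective regularization), and
``"global_mean"`` (mean over all samples -- the strongest effective
regularization; at alpha = 0.01 it visibly shrinks the model).  Since Adam
is invariant to the overall loss scale, the choice only sets the relative
weight of the L1 penalty.

Every protocol stress is a linear functional of the eight energy
derivatives with coefficients affine in the kappas, so the loss gradient is
available in closed form for both the weights and the kappa parameters;
training runs minibatch Adam with a non-negativity projection after every
step and early stopping on the full training loss.  Trainable kappas are
parameterized through a scaled logistic onto [0, 1/3].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constitutive import ModelWeights
from .dispersion import DispersionParams
from .protocols import Dataset
from .stress import biaxial_coefficients, shear_coefficients

__all__ = [
    "TrainingConfig",
    "DiscoveredModel",
    "loss",
    "predict",
    "init_weights",
    "train",
    "discover_kappa",
    "fit_kappa_fixed_weights",
    "r_squared",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the discovery run.

    alpha:          L1 regularization weight on the 48 energy weights.
    max_epochs:     hard cap on training epochs.
    batch_size:     minibatch size for Adam.
    patience:       stop when the full training loss has not improved by
                    ``min_improvement`` for this many consecutive epochs.
    learning_rate:  Adam step size.
    kappa_mode:     "fixed" trains weights at the supplied kappas;
                    "trainable" also learns kappa_f/s/n in [0, 1/3].
    restarts:       independent random initializations; best final loss wins.
    """

    alpha: float = 0.01
    max_epochs: int = 30_000
    batch_size: int = 32
    patience: int = 1_000
    learning_rate: float = 0.001
    seed: int = 0
    kappa_mode: str = "fixed"
    restarts: int = 3
    min_improvement: float = 1e-8
    loss_normalization: str = "sum"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.loss_normalization not in ("sum", "per_channel", "global_mean"):
            raise ValueError(
                "loss_normalization must be 'sum', 'per_channel' or 'global_mean'")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.kappa_mode not in ("fixed", "trainable"):
            raise ValueError("kappa_mode must be 'fixed' or 'trainable'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class DiscoveredModel:
    """Result of a discovery run."""

    weights: ModelWeights
    kappas: DispersionParams
    r2_channels: dict[tuple[str, str], float]
    r2_mean: float
    active_terms: list[int]
    loss: float
    epochs_run: int
    config: TrainingConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# design matrices


_SHEAR_PREFIX = "shear-"
_UNIT_KAPPAS = ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


class _Design:
    """Per-sample arrays the trainer needs.

    raw:   (n, 8) raw invariants (I1, I2, I4f, I4s, I4n, I8fs, I8fn, I8sn)
    mask:  (n, 8) tension-switch multiplier
    coeff: (4, n, 8) kappa-affine stress-coefficient decomposition
           C(kappa) = coeff[0] + kf*coeff[1] + ks*coeff[2] + kn*coeff[3]
    y:     (n,) measured stresses [kPa]
    """

    def __init__(self, dataset: Dataset):
        tbl = dataset.table
        n = len(tbl)
        self.raw = np.empty((n, 8))
        self.mask = np.ones((n, 8))
        self.coeff = np.zeros((4, n, 8))
        self.y = tbl["stress_kPa"].to_numpy().astype(float)
        self.channel_index = dict(dataset.channel_groups())
        self.channel_size = np.empty(n)
        for _, rows in self.channel_index.items():
            self.channel_size[rows] = len(rows)

        proto = tbl["protocol"].to_numpy()
        mode = tbl["mode_or_ratio"].to_numpy()
        a = tbl["strain_or_stretch_f"].to_numpy().astype(float)
        b = tbl["stretch_n"].to_numpy().astype(float)
        chan = tbl["channel"].to_numpy()

        shear = np.char.startswith(proto.astype(str), _SHEAR_PREFIX)
        # shear rows: a = gamma
        if np.any(shear):
            g = a[shear]
            self.raw[shear, 0] = self.raw[shear, 1] = 3.0 + g**2
            self.raw[shear, 2:] = 0.0
            self.raw[shear, 2:5] = 1.0
            for m in np.unique(mode[shear]):
                rows = np.where(shear & (mode == m))[0]
                i, j = m
                stretch_axis = {"f": 2, "s": 3, "n": 4}[i]
                i8_axis = {frozenset("fs"): 5, frozenset("fn"): 6, frozenset("sn"): 7}[frozenset(m)]
                self.raw[rows, stretch_axis] = 1.0 + a[rows] ** 2
                self.raw[rows, i8_axis] = a[rows]
                for q, kap in enumerate(_UNIT_KAPPAS):
                    c = shear_coefficients(m, a[rows], kap)
                    self.coeff[q, rows] = c if q == 0 else c - self.coeff[0, rows]
        # biaxial rows: a = lambda_f, b = lambda_n
        biax = ~shear
        if np.any(biax):
            lf, ln = a[biax], b[biax]
            ls = 1.0 / (lf * ln)
            self.raw[biax, 0] = lf**2 + ls**2 + ln**2
            self.raw[biax, 1] = (lf * ls) ** 2 + (lf * ln) ** 2 + (ls * ln) ** 2
            self.raw[biax, 2] = lf**2
            self.raw[biax, 3] = ls**2
            self.raw[biax, 4] = ln**2
            self.raw[biax, 5:] = 0.0
            rows = np.where(biax)[0]
            is_ff = chan[rows] == "sigma_ff"
            for q, kap in enumerate(_UNIT_KAPPAS):
                c_ff, c_nn = biaxial_coefficients(lf, ln, kap)
                c = np.where(is_ff[:, None], c_ff, c_nn)
                self.coeff[q, rows] = c if q == 0 else c - self.coeff[0, rows]
        # tension switch on the undispersed I4
        self.mask[:, 2:5] = (self.raw[:, 2:5] >= 1.0).astype(float)

    @property
    def n(self) -> int:
        return len(self.y)

    def sample_weights(self, normalization: str) -> np.ndarray:
        """Per-sample weights omega with objective sum_i omega_i * r_i^2."""
        if normalization == "sum":
            return np.ones(self.n)
        if normalization == "per_channel":
            return 1.0 / self.channel_size
        if normalization == "global_mean":
            return np.full(self.n, 1.0 / self.n)
        raise ValueError(f"unknown loss normalization {normalization!r}")

    def bases(self, kappa: np.ndarray, idx=slice(None)) -> np.ndarray:
        """Corrected network inputs x (n, 8) at a kappa triple."""
        raw = self.raw[idx]
        x = raw.copy()
        x[:, 0] -= 3.0
        x[:, 1] -= 3.0
        x[:, 2:5] = kappa * raw[:, [0]] + (1.0 - 3.0 * kappa) * raw[:, 2:5] - 1.0
        return x

    def coefficients(self, kappa: np.ndarray, idx=slice(None)) -> np.ndarray:
        c = self.coeff[:, idx]
        return c[0] + kappa[0] * c[1] + kappa[1] * c[2] + kappa[2] * c[3]


def _unpack(w: np.ndarray):
    return w[0:8], w[8:16], w[16:24], w[24:32], w[32:40], w[40:48]


def _predict_from(design: _Design, w: np.ndarray, kappa: np.ndarray, idx=slice(None)):
    """Model stresses and intermediates for the rows in idx."""
    lin1, e1w1, e1w2, lin2, e2w1, e2w2 = _unpack(w)
    x = design.bases(kappa, idx) * design.mask[idx]
    c = design.coefficients(kappa, idx) * design.mask[idx]
    E1 = np.exp(e1w1 * x)
    E2 = np.exp(e2w1 * x**2)
    g = lin1 + e1w1 * e1w2 * E1 + 2.0 * lin2 * x + 2.0 * e2w1 * e2w2 * x * E2
    sigma = np.einsum("nk,nk->n", c, g)
    return sigma, x, c, E1, E2, g


def _loss_value(design: _Design, w: np.ndarray, kappa: np.ndarray, alpha: float,
                omega: np.ndarray) -> float:
    sigma, *_ = _predict_from(design, w, kappa)
    return float(omega @ (sigma - design.y) ** 2 + alpha * np.sum(np.abs(w)))


def _gradients(design: _Design, w: np.ndarray, kappa: np.ndarray, alpha: float, idx,
               kappa_grad: bool, omega: np.ndarray):
    """Analytic gradient of the (unbiased) batch loss w.r.t. w (48,) and kappa (3,)."""
    lin1, e1w1, e1w2, lin2, e2w1, e2w2 = _unpack(w)
    sigma, x, c, E1, E2, g = _predict_from(design, w, kappa, idx)
    r = sigma - design.y[idx]
    nb = len(r)
    scale = 2.0 * design.n / nb
    wr = scale * omega[idx] * r
    A = wr[:, None] * c  # (nb, 8)
    gw = np.concatenate([
        A.sum(0),
        (A * e1w2 * E1 * (1.0 + e1w1 * x)).sum(0),
        (A * e1w1 * E1).sum(0),
        (A * 2.0 * x).sum(0),
        (A * 2.0 * e2w2 * x * E2 * (1.0 + e2w1 * x**2)).sum(0),
        (A * 2.0 * e2w1 * x * E2).sum(0),
    ]) + alpha
    if not kappa_grad:
        return gw, None
    # dg/dx per row, and kappa-sensitivity of bases and coefficients
    gp = e1w1**2 * e1w2 * E1 + 2.0 * lin2 + 2.0 * e2w1 * e2w2 * E2 * (1.0 + 2.0 * e2w1 * x**2)
    raw = design.raw[idx]
    m = design.mask[idx]
    dx = (raw[:, [0]] - 3.0 * raw[:, 2:5]) * m[:, 2:5]  # d base / d kappa_i, i4 rows
    rA = wr
    gk = np.empty(3)
    for i in range(3):
        dC = design.coeff[1 + i][idx] * m
        via_c = np.einsum("nk,nk->n", dC, g)
        via_x = c[:, 2 + i] * gp[:, 2 + i] * dx[:, i]
        gk[i] = rA @ (via_c + via_x)
    return gw, gk


# ---------------------------------------------------------------------------
# public API


def loss(
    weights: ModelWeights,
    kappas: DispersionParams,
    dataset: Dataset,
    alpha: float = 0.01,
    normalization: str = "global_mean",
) -> float:
    """The regularized stress-misfit loss.

    With the default ``normalization="global_mean"`` this is the mean squared
    stress error over all samples plus alpha * L1(weights); ``"per_channel"``
    averages within each stress channel and sums across channels (the
    trainer's default objective).
    """
    design = _Design(dataset)
    omega = design.sample_weights(normalization)
    return _loss_value(design, weights.to_vector(), kappas.as_array(), alpha, omega)


def predict(
    weights: ModelWeights, kappas: DispersionParams, dataset: Dataset
) -> np.ndarray:
    """Model stresses [kPa] for every sample row of the dataset."""
    design = _Design(dataset)
    sigma, *_ = _predict_from(design, weights.to_vector(), kappas.as_array())
    return sigma


def init_weights(seed: int | np.random.Generator) -> ModelWeights:
    """Random initial weights: Glorot-normal (clamped at zero) for the
    collapsed identity-activation weights, uniform on [0, 0.1] for the
    exponential (inner, outer) pairs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lin1 = np.clip(rng.normal(0.0, 1.0, 8), 0.0, None)
    lin2 = np.clip(rng.normal(0.0, 1.0, 8), 0.0, None)
    exp1 = rng.uniform(0.0, 0.1, (8, 2))
    exp2 = rng.uniform(0.0, 0.1, (8, 2))
    return ModelWeights(lin1=lin1, exp1=exp1, lin2=lin2, exp2=exp2)


def r_squared_from_predictions(
    pred: np.ndarray, dataset: Dataset
) -> tuple[dict[tuple[str, str], float], float]:
    """Coefficient of determination per stress channel and its unweighted mean.

    R^2 = 1 - SS_res / SS_tot about each channel's mean; channels with zero
    variance are excluded with a warning.
    """
    y = dataset.stresses
    out: dict[tuple[str, str], float] = {}
    for key, idx in dataset.channel_groups():
        ss_tot = float(np.sum((y[idx] - np.mean(y[idx])) ** 2))
        if ss_tot == 0.0:
            warnings.warn(f"channel {key} has zero variance; excluded from R^2")
            continue
        ss_res = float(np.sum((y[idx] - pred[idx]) ** 2))
        out[key] = 1.0 - ss_res / ss_tot
    mean = float(np.mean(list(out.values()))) if out else float("nan")
    return out, mean


def r_squared(
    weights: ModelWeights, kappas: DispersionParams, dataset: Dataset
) -> tuple[dict[tuple[str, str], float], float]:
    """Per-channel and mean R^2 of a model's predictions on a dataset."""
    return r_squared_from_predictions(predict(weights, kappas, dataset), dataset)


def _kappa_from_latent(z: np.ndarray) -> np.ndarray:
    return (1.0 / 3.0) / (1.0 + np.exp(-z))


def _run_restart(design: _Design, config: TrainingConfig, rng: np.random.Generator,
                 kappa_fixed: np.ndarray, z0: np.ndarray | None):
    trainable = config.kappa_mode == "trainable"
    omega = design.sample_weights(config.loss_normalization)
    w = init_weights(rng).to_vector()
    z = None if not trainable else np.array(z0, float)
    n_par = 48 + (3 if trainable else 0)
    m_adam = np.zeros(n_par)
    v_adam = np.zeros(n_par)
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    t = 0
    n = design.n
    best_loss = np.inf
    best_w, best_z = w.copy(), None if z is None else z.copy()
    stall = 0
    epoch = 0
    losses = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            kappa = kappa_fixed if z is None else _kappa_from_latent(z)
            gw, gk = _gradients(design, w, kappa, config.alpha, idx,
                                kappa_grad=trainable, omega=omega)
            grad = gw if gk is None else np.concatenate([gw, gk * kappa * (1.0 - 3.0 * kappa)])
            t += 1
            m_adam = beta1 * m_adam + (1 - beta1) * grad
            v_adam = beta2 * v_adam + (1 - beta2) * grad**2
            step = (config.learning_rate * (m_adam / (1 - beta1**t))
                    / (np.sqrt(v_adam / (1 - beta2**t)) + eps))
            w = np.clip(w - step[:48], 0.0, None)
            if trainable:
                z = z - step[48:]
        kappa = kappa_fixed if z is None else _kappa_from_latent(z)
        cur = _loss_value(design, w, kappa, config.alpha, omega)
        losses.append(cur)
        if not np.isfinite(cur):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={cur}, max weight={w.max():.3g}"
            )
        if best_loss - cur > config.min_improvement:
            best_loss = cur
            best_w = w.copy()
            if trainable:
                best_z = z.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    kappa = kappa_fixed if best_z is None else _kappa_from_latent(best_z)
    return best_loss, best_w, kappa, epoch, losses


def train(
    dataset: Dataset,
    config: TrainingConfig | None = None,
    kappas: DispersionParams | None = None,
    active_threshold: float = 0.005,
) -> DiscoveredModel:
    """Discover a sparse model from a stress dataset.

    ``kappas`` are the dispersion parameters used by the network (ignored as
    starting values when ``config.kappa_mode == 'trainable'``).  Runs
    ``config.restarts`` independent initializations and keeps the best final
    loss.  Raises FloatingPointError only if every restart diverges.
    """
    from .protocols import report_active_terms  # local import; avoids cycle

    config = config or TrainingConfig()
    kappa_fixed = (kappas or DispersionParams()).as_array()
    design = _Design(dataset)
    results = []
    history = []
    for r in range(config.restarts):
        rng = np.random.default_rng([config.seed % (2**31), r])
        # first restart starts the latent kappas at mid-range, later ones randomly
        z0 = np.zeros(3) if r == 0 else rng.normal(0.0, 1.0, 3)
        try:
            res = _run_restart(design, config, rng, kappa_fixed, z0)
        except FloatingPointError as err:
            warnings.warn(f"restart {r} aborted: {err}")
            continue
        results.append(res)
        history.extend(
            {"restart": r, "epoch": e + 1, "loss": lv} for e, lv in enumerate(res[4])
        )
    if not results:
        raise FloatingPointError("all restarts diverged")
    best_loss, best_w, kappa, epochs, _ = min(results, key=lambda r: r[0])
    weights = ModelWeights.from_vector(best_w)
    kappas_out = DispersionParams(*kappa)
    r2_channels, r2_mean = r_squared(weights, kappas_out, dataset)
    report = report_active_terms(weights, kappas_out, threshold=active_threshold)
    return DiscoveredModel(
        weights=weights,
        kappas=kappas_out,
        r2_channels=r2_channels,
        r2_mean=r2_mean,
        active_terms=list(report["node"]) if len(report) else [],
        loss=best_loss,
        epochs_run=epochs,
        config=config,
        history=pd.DataFrame(history),
    )


def fit_kappa_fixed_weights(
    weights: ModelWeights,
    dataset: Dataset,
    kappa0: tuple[float, float, float] = (1 / 6, 1 / 6, 1 / 6),
) -> DispersionParams:
    """Least-squares fit of the dispersion parameters at fixed energy weights.

    Unlike joint discovery -- where retrainable weights can absorb the effect
    of dispersion almost exactly, leaving the kappas unidentifiable -- fixing
    the weights makes the three kappas a well-posed bounded least-squares
    problem, solved with L-BFGS-B on [0, 1/3]^3.
    """
    from scipy.optimize import minimize

    design = _Design(dataset)
    wv = weights.to_vector()
    omega = np.ones(design.n)

    def objective(kappa):
        return _loss_value(design, wv, kappa, 0.0, omega)

    res = minimize(
        objective,
        x0=np.asarray(kappa0, float),
        method="L-BFGS-B",
        bounds=[(0.0, 1.0 / 3.0)] * 3,
    )
    return DispersionParams(*res.x)


def discover_kappa(
    dataset: Dataset, config: TrainingConfig | None = None
) -> DiscoveredModel:
    """Train with kappa_f, kappa_s, kappa_n as additional parameters in [0, 1/3]."""
    config = config or TrainingConfig()
    return train(dataset, replace(config, kappa_mode="trainable"))
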