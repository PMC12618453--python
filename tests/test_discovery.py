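import numpy as np
import pandas as pd
import pytest

from dispercann.catalog import get_model
from dispercann.constitutive import ModelWeights
from dispercann.dispersion import DispersionParams
from dispercann.discovery import (
    TrainingConfig,
    fit_kappa_fixed_weights,
    init_weights,
    loss,
    predict,
    r_squared,
    r_squared_from_predictions,
    train,
)
from dispercann.protocols import Dataset, default_protocols, simulate_dataset

K0 = DispersionParams()


def toy_dataset(stresses, gammas=None):
    gammas = gammas if gammas is not None else np.linspace(0.1, 0.5, len(stresses))
    return Dataset(
        pd.DataFrame(
            {
                "protocol": "shear-fs",
                "mode_or_ratio": "fs",
                "strain_or_stretch_f": gammas,
                "stretch_n": 1.0,
                "channel": "sigma_fs",
                "stress_kPa": stresses,
            }
        )
    )


def test_loss_zero_for_generating_model():
    m = get_model("equal", "0")
    ds = simulate_dataset(m.weights, m.kappas)
    assert loss(m.weights, m.kappas, ds, alpha=0.0) == pytest.approx(0.0, abs=1e-20)


def test_loss_of_zero_model_is_mean_squared_stress():
    ds = simulate_dataset(get_model("equal", "0").weights, K0)
    want = float(np.mean(ds.stresses**2))
    assert loss(ModelWeights(), K0, ds, alpha=0.0) == pytest.approx(want, rel=1e-12)


def test_loss_two_point_hand_computation():
    """Hand oracle on two shear-fs points with a linear I1 model:
    sigma = 2 gamma c, so residuals and the L1 term follow by arithmetic."""
    c = 2.0
    w = ModelWeights.from_terms({1: c})
    ds = toy_dataset([1.0, 3.0], gammas=np.array([0.25, 0.5]))
    # predictions: 2*0.25*2 = 1.0 (exact), 2*0.5*2 = 2.0 -> residual 1
    want_mean = (0.0 + 1.0) / 2.0 + 0.5 * c  # alpha = 0.5
    assert loss(w, K0, ds, alpha=0.5) == pytest.approx(want_mean, rel=1e-12)
    want_sum = (0.0 + 1.0) + 0.5 * c
    assert loss(w, K0, ds, alpha=0.5, normalization="sum") == pytest.approx(want_sum, rel=1e-12)
    assert np.allclose(predict(w, K0, ds), [1.0, 2.0])


def test_init_weights_contract():
    a = init_weights(7)
    b = init_weights(7)
    assert np.array_equal(a.to_vector(), b.to_vector())  # deterministic per seed
    v = a.to_vector()
    assert np.all(v >= 0.0)
    assert np.all(a.exp1 <= 0.1) and np.all(a.exp2 <= 0.1)
    assert np.any(init_weights(8).to_vector() != v)


def test_r_squared_definitions():
    ds = toy_dataset([1.0, 2.0, 3.0])
    channels, mean = r_squared_from_predictions(np.array([1.0, 2.0, 4.0]), ds)
    assert mean == pytest.approx(0.5)
    assert channels[("shear-fs", "sigma_fs")] == pytest.approx(0.5)
    # predicting the channel mean gives zero
    _, zero = r_squared_from_predictions(np.full(3, 2.0), ds)
    assert zero == pytest.approx(0.0)
    # perfect prediction gives one
    _, one = r_squared_from_predictions(np.array([1.0, 2.0, 3.0]), ds)
    assert one == pytest.approx(1.0)


def test_r_squared_excludes_zero_variance_channels():
    ds = toy_dataset([2.0, 2.0, 2.0])
    with pytest.warns(UserWarning, match="zero variance"):
        _, mean = r_squared_from_predictions(np.zeros(3), ds)
    assert np.isnan(mean)


def quick_config(**kw):
    base = dict(seed=3, restarts=1, max_epochs=2500, patience=600)
    base.update(kw)
    return TrainingConfig(**base)


def test_single_term_ground_truth_dominates():
    """Data from a one-term model: that term's invariant dominates the
    recovered energy, measured by peak stress contribution."""
    from dispercann.protocols import report_active_terms

    truth = ModelWeights.from_terms({7: 4.0})  # quadratic I2
    protos = default_protocols(n_points=9)
    ds = simulate_dataset(truth, K0, protos)
    res = train(ds, quick_config(max_epochs=8000, patience=2000))
    assert res.r2_mean > 0.99
    rep = report_active_terms(res.weights, res.kappas, protocols=protos, threshold=0.0)
    by_inv = rep.groupby("invariant")["peak_stress_kPa"].max()
    assert by_inv.idxmax() == "I2"
    others = by_inv.drop("I2").max()
    assert others < 0.05 * by_inv["I2"]


def test_training_loss_best_so_far_is_monotone():
    m = get_model("equal", "0")
    ds = simulate_dataset(m.weights, m.kappas, default_protocols(n_points=9))
    res = train(ds, quick_config(max_epochs=400, patience=200))
    curve = res.history[res.history["restart"] == 0]["loss"].to_numpy()
    best = np.minimum.accumulate(curve)
    assert res.loss <= best[-1] + 1e-12
    assert np.all(np.diff(best) <= 0)


def test_more_regularization_never_adds_terms():
    """Sparsity direction: the active-term count is non-increasing in alpha."""
    m = get_model("equal", "0")
    ds = simulate_dataset(m.weights, m.kappas, default_protocols(n_points=9))
    counts = []
    for alpha in (0.001, 0.01, 0.1):
        res = train(ds, quick_config(alpha=alpha, max_epochs=1500, patience=500))
        counts.append(len(res.active_terms))
    assert counts[0] >= counts[1] >= counts[2]


def test_trainable_kappa_stays_in_bounds():
    m = get_model("equal", "0")
    ds = simulate_dataset(m.weights, DispersionParams(0.1, 0.1, 0.1),
                          default_protocols(n_points=9))
    from dispercann.discovery import discover_kappa

    res = discover_kappa(ds, quick_config(max_epochs=600, patience=300))
    k = res.kappas.as_array()
    assert np.all(k >= 0.0) and np.all(k <= 1 / 3 + 1e-12)


def test_fixed_weight_kappa_fit_is_well_posed():
    gen = ModelWeights.from_terms({7: 5.0, 12: (21.0, 0.08), 16: (15.0, 0.12), 20: (12.0, 0.2)})
    truth = DispersionParams(0.05, 0.15, 0.3)
    ds = simulate_dataset(gen, truth)
    rec = fit_kappa_fixed_weights(gen, ds)
    assert np.allclose(rec.as_array(), truth.as_array(), atol=1e-4)


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(alpha=-0.1)
    with pytest.raises(ValueError):
        TrainingConfig(patience=40000)
    with pytest.raises(ValueError):
        TrainingConfig(kappa_mode="bogus")
    with pytest.raises(ValueError):
        TrainingConfig(loss_normalization="bogus")


def test_training_is_deterministic_per_seed():
    m = get_model("equal", "0")
    ds = simulate_dataset(m.weights, m.kappas, default_protocols(n_points=7))
    cfg = quick_config(max_epochs=300, patience=150)
    a = train(ds, cfg)
    b = train(ds, cfg)
    assert np.array_equal(a.weights.to_vector(), b.weights.to_vector())
    assert a.loss == b.loss
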