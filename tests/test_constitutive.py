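import json

import numpy as np
import pytest

from dispercann.constitutive import (
    EXP_GUARD,
    INVARIANT_LABELS,
    ModelWeights,
    corrected_bases,
    energy_gradients,
    free_energy,
    load_model,
    node_term,
    save_model,
    tension_switch,
    term_label,
)
from dispercann.dispersion import DispersionParams
from dispercann.kinematics import (
    ShearState,
    biaxial_deformation_gradient,
    compute_invariants,
    shear_deformation_gradient,
)


def test_node_layout_matches_energy_table():
    """Row k of the 8 invariants owns nodes 4k+1..4k+4 in the fixed order
    (identity, exp) x (power 1, power 2)."""
    assert node_term(1) == (0, 1, "identity")
    assert node_term(2) == (0, 1, "exp")
    assert node_term(7) == (1, 2, "identity")
    assert node_term(12) == (2, 2, "exp")
    assert node_term(32) == (7, 2, "exp")
    assert term_label(12) == "exp([I4f*-1]^2)"
    assert term_label(7) == "[I2-3]^2"
    with pytest.raises(ValueError):
        node_term(33)


def test_weights_roundtrip_bit_exact(tmp_path, random_weights):
    v = random_weights.to_vector()
    assert v.shape == (48,)
    assert np.array_equal(ModelWeights.from_vector(v).to_vector(), v)
    d = random_weights.to_dict()
    assert len(d) == 48
    assert np.array_equal(ModelWeights.from_dict(d).to_vector(), v)
    path = tmp_path / "model.json"
    save_model(path, random_weights, DispersionParams(0.1, 0.2, 0.3), {"note": "x"})
    w2, k2, meta = load_model(path)
    assert np.array_equal(w2.to_vector(), v)  # bit-exact through JSON
    assert (k2.kappa_f, k2.kappa_s, k2.kappa_n) == (0.1, 0.2, 0.3)
    assert meta == {"note": "x"}


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        ModelWeights(lin1=np.full(8, -0.1))


def test_tension_switch():
    # identity: all flags on (the boundary I4 = 1 is inclusive)
    flags = tension_switch(compute_invariants(np.eye(3)))
    assert flags.active_f and flags.active_s and flags.active_n
    # equibiaxial stretch compresses the sheet direction
    flags = tension_switch(compute_invariants(biaxial_deformation_gradient(1.05, 1.05)))
    assert flags.active_f and flags.active_n and not flags.active_s
    # fs shear stretches the fiber direction
    flags = tension_switch(
        compute_invariants(shear_deformation_gradient(ShearState("fs", 0.3)))
    )
    assert flags.active_f


def test_energy_zero_at_rest_and_for_zero_weights(random_weights):
    x, mask = corrected_bases(compute_invariants(np.eye(3)), DispersionParams(0.1, 0.2, 0.3))
    assert free_energy(x, random_weights, mask) == 0.0
    x2, m2 = corrected_bases(
        compute_invariants(shear_deformation_gradient(ShearState("fn", 0.4)))
    )
    assert free_energy(x2, ModelWeights(), m2) == 0.0
    assert free_energy(x2, random_weights, m2) >= 0.0


def test_single_exponential_term_value():
    """One active exp([I4f*-1]^2) node against an arbitrary-precision oracle."""
    import mpmath

    mpmath.mp.dps = 40
    w = ModelWeights.from_terms({12: (21.062, 0.081)})
    x = np.zeros(8)
    x[2] = 0.2  # I4f* = 1.2
    expected = mpmath.mpf("0.081") * (mpmath.e ** (mpmath.mpf("21.062") * mpmath.mpf("0.04")) - 1)
    assert free_energy(x, w) == pytest.approx(float(expected), rel=1e-12)


def test_quadratic_identity_gradient():
    w = ModelWeights.from_terms({3: 2.5})  # 2.5 * [I1-3]^2
    x = np.zeros(8)
    x[0] = 0.3
    g = energy_gradients(x, w)
    assert g[0] == pytest.approx(2 * 2.5 * 0.3, rel=1e-14)
    assert np.all(energy_gradients(x, ModelWeights()) == 0.0)


@pytest.mark.parametrize("j", range(1, 33))
def test_gradients_match_finite_differences_per_term(j, rng):
    """Each of the 32 terms: d psi / d I_k by central differences, 1e-6 relative."""
    vals = (0.7, 0.9) if node_term(j)[2] == "exp" else (1.3,)
    w = ModelWeights.from_terms({j: vals})
    x = rng.uniform(-0.3, 0.3, 8)
    g = energy_gradients(x, w)
    h = 1e-6
    for k in range(8):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        fd = (free_energy(xp, w) - free_energy(xm, w)) / (2 * h)
        assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_switched_rows_contribute_nothing(random_weights):
    inv = compute_invariants(biaxial_deformation_gradient(1.08, 1.02))
    kap = DispersionParams(0.1, 0.1, 0.1)
    x, mask = corrected_bases(inv, kap)
    assert mask[3] == 0.0  # sheet row off under compression
    g = energy_gradients(x, random_weights, mask)
    assert g[3] == 0.0
    # energy equals the energy with the sheet row weights deleted
    w2 = ModelWeights.from_vector(random_weights.to_vector())
    w2.lin1[3] = w2.lin2[3] = 0.0
    w2.exp1[3] = w2.exp2[3] = 0.0
    assert free_energy(x, random_weights, mask) == pytest.approx(
        free_energy(x, w2, np.ones(8)), rel=1e-12
    )


def test_zero_kappa_reduces_to_undispersed_inputs(random_weights, rng):
    """With kappa = 0 the network inputs equal the raw invariant corrections."""
    inv = compute_invariants(shear_deformation_gradient(ShearState("sn", 0.25)))
    x0, m0 = corrected_bases(inv, DispersionParams())
    raw = np.array([inv.I1 - 3, inv.I2 - 3, inv.I4f - 1, inv.I4s - 1, inv.I4n - 1,
                    inv.I8fs, inv.I8fn, inv.I8sn])
    assert np.allclose(x0, raw, atol=1e-15)


def test_exponent_guard_raises():
    w = ModelWeights.from_terms({2: (300.0, 1.0)})
    x = np.zeros(8)
    x[0] = 0.5
    with pytest.raises(OverflowError):
        free_energy(x, w)


def test_invariant_labels_cover_all_rows():
    assert len(INVARIANT_LABELS) == 8
    assert EXP_GUARD == 50.0
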