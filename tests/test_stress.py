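import numpy as np
import pytest

from dispercann.constitutive import ModelWeights, corrected_bases, free_energy
from dispercann.dispersion import DispersionParams
from dispercann.kinematics import (
    SHEAR_MODES,
    DeformationGradient,
    ShearState,
    biaxial_deformation_gradient,
    compute_invariants,
    shear_deformation_gradient,
)
from dispercann.stress import (
    biaxial_stresses,
    cauchy_stress_general,
    plane_stress_pressure,
    shear_stress,
)

AX = {"f": 0, "s": 1, "n": 2}


def finite_difference_stress(F, weights, kappas, p, h=1e-6):
    """Oracle: sigma = (d psi / d F) . F^T - p I by central differences."""

    def psi(Fm):
        inv = compute_invariants(DeformationGradient(Fm))
        x, mask = corrected_bases(inv, kappas)
        return free_energy(x, weights, mask)

    G = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[a, b] += h
            Fm[a, b] -= h
            G[a, b] = (psi(Fp) - psi(Fm)) / (2 * h)
    return G @ F.T - p * np.eye(3)


@pytest.mark.parametrize("mode", SHEAR_MODES)
@pytest.mark.parametrize("gamma", [0.1, 0.3, 0.5])
def test_shear_closed_form_equals_general_stress(mode, gamma, random_weights, kappas):
    """The closed-form shear stress is the (i,j) component of the general
    Cauchy stress; this equality also pins the shear convention."""
    F = shear_deformation_gradient(ShearState(mode, gamma))
    sigma = cauchy_stress_general(F, random_weights, kappas).sigma
    assert np.allclose(sigma, sigma.T, atol=1e-10)
    i, j = mode
    closed = shear_stress(mode, gamma, random_weights, kappas)
    assert closed == pytest.approx(sigma[AX[i], AX[j]], rel=1e-8)
    assert closed == pytest.approx(sigma[AX[j], AX[i]], rel=1e-8)


def test_general_stress_matches_finite_difference_oracle(random_weights, kappas, rng):
    """Full-tensor agreement for states with every I4 strictly off the tension
    switch boundary (with dispersion the energy is discontinuous exactly at
    I4 = 1, where central differences are meaningless); off-diagonal
    agreement for the shear states, which sit on that boundary in the two
    unstretched directions."""
    generic = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    generic /= np.linalg.det(generic) ** (1 / 3)
    for F in (biaxial_deformation_gradient(1.07, 1.04).F, generic):
        p = 1.3
        sigma = cauchy_stress_general(F, random_weights, kappas, p=p).sigma
        oracle = finite_difference_stress(F, random_weights, kappas, p)
        assert np.allclose(sigma, oracle, rtol=1e-6, atol=1e-6)
    for mode, gamma in (("fs", 0.35), ("ns", 0.2)):
        F = shear_deformation_gradient(ShearState(mode, gamma)).F
        sigma = cauchy_stress_general(F, random_weights, kappas, p=0.0).sigma
        oracle = finite_difference_stress(F, random_weights, kappas, p=0.0)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(sigma[off], oracle[off], rtol=1e-6, atol=1e-6)


def test_plane_stress_pressure_annihilates_sheet_stress(random_weights, kappas):
    for lf, ln in [(1.02, 1.01), (1.1, 1.1), (1.08, 1.004)]:
        F = biaxial_deformation_gradient(lf, ln)
        p = plane_stress_pressure(F, random_weights, kappas)
        sigma = cauchy_stress_general(F, random_weights, kappas, p=p).sigma
        assert abs(sigma[1, 1]) <= 1e-10
        s_ff, s_nn = biaxial_stresses(lf, ln, random_weights, kappas)
        assert s_ff == pytest.approx(sigma[0, 0], rel=1e-10, abs=1e-12)
        assert s_nn == pytest.approx(sigma[2, 2], rel=1e-10, abs=1e-12)


def test_rest_state_is_stress_free(second_order_weights, kappas):
    """With no first-order anisotropic terms, the rest pressure
    p = 2 dpsi/dI1 + 4 dpsi/dI2 makes sigma(I) vanish identically."""
    from dispercann.constitutive import energy_gradients

    x, mask = corrected_bases(compute_invariants(np.eye(3)), kappas)
    g = energy_gradients(x, second_order_weights, mask)
    p0 = 2.0 * g[0] + 4.0 * g[1]
    sigma = cauchy_stress_general(np.eye(3), second_order_weights, kappas, p=p0).sigma
    assert np.allclose(sigma, 0.0, atol=1e-12)
    assert biaxial_stresses(1.0, 1.0, second_order_weights, kappas) == pytest.approx(
        (0.0, 0.0), abs=1e-12
    )
    for mode in SHEAR_MODES:
        assert shear_stress(mode, 0.0, second_order_weights, kappas) == pytest.approx(
            0.0, abs=1e-12
        )


def test_linear_isotropic_shear_response():
    """Only a linear I1 term with effective weight c: sigma_ij = 2 gamma c."""
    c = 1.7
    w = ModelWeights.from_terms({1: c})
    for gamma in (0.1, 0.4):
        assert shear_stress("sf", gamma, w) == pytest.approx(2 * gamma * c, rel=1e-12)


def test_dispersion_free_shear_drops_second_fourth_invariant():
    """At kappa_i = kappa_j = 0 only the stretched direction's I4 enters."""
    w = ModelWeights.from_terms({13: 2.0})  # linear I4s* term
    # mode fs: j = s; its I4s* contribution is scaled by kappa_s
    assert shear_stress("fs", 0.3, w, DispersionParams(0, 0, 0)) == pytest.approx(0.0, abs=1e-14)
    assert shear_stress("fs", 0.3, w, DispersionParams(0, 0.1, 0)) != pytest.approx(0.0, abs=1e-6)


def test_equal_biaxial_stresses_under_isotropic_dispersion(random_weights):
    """kappa = 1/3 everywhere removes directional distinction: for lambda_f =
    lambda_n the two normal stresses coincide."""
    kap = DispersionParams(1 / 3, 1 / 3, 1 / 3)
    s_ff, s_nn = biaxial_stresses(1.08, 1.08, random_weights, kap)
    assert s_ff == pytest.approx(s_nn, rel=1e-10)


def test_quadratic_i2_biaxial_closed_form():
    """kappa = 0, quadratic-I2-only model reduces to
    sigma_ff = 2 dpsi/dI2 (lf^2 - ls^2) ln^2, sigma_nn = 2 dpsi/dI2 (ln^2 - ls^2) lf^2."""
    w = ModelWeights.from_terms({7: 3.0})
    lf, ln = 1.1, 1.0
    ls = 1 / (lf * ln)
    inv = compute_invariants(biaxial_deformation_gradient(lf, ln))
    dpsi_dI2 = 2 * 3.0 * (inv.I2 - 3)
    s_ff, s_nn = biaxial_stresses(lf, ln, w)
    assert s_ff == pytest.approx(2 * dpsi_dI2 * (lf**2 - ls**2) * ln**2, rel=1e-12)
    assert s_nn == pytest.approx(2 * dpsi_dI2 * (ln**2 - ls**2) * lf**2, rel=1e-12)


def test_printed_variant_differs_only_in_documented_terms(random_weights, kappas):
    """The printed truncation omits anisotropic pressure terms (biaxial) and
    scales the coupling contribution by gamma (shear)."""
    exact = shear_stress("fs", 0.3, random_weights, kappas, form="exact")
    printed = shear_stress("fs", 0.3, random_weights, kappas, form="printed")
    assert exact != pytest.approx(printed, rel=1e-6)
    # without I8 and out-of-plane terms the two shear forms coincide
    w = ModelWeights.from_terms({7: 2.0, 11: 1.5})
    kap0 = DispersionParams(0.2, 0.0, 0.0)
    assert shear_stress("fs", 0.3, w, kap0, form="exact") == pytest.approx(
        shear_stress("fs", 0.3, w, kap0, form="printed"), rel=1e-12
    )
    with pytest.raises(ValueError):
        shear_stress("fs", 0.3, random_weights, kappas, form="bogus")
    b_exact = biaxial_stresses(1.06, 1.03, random_weights, kappas, form="exact")
    b_printed = biaxial_stresses(1.06, 1.03, random_weights, kappas, form="printed")
    assert b_exact[0] != pytest.approx(b_printed[0], rel=1e-8)
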