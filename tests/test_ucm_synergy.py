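import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ucmbalance.chain_vars import RelativeXcom, reconstruct
from ucmbalance.ucm_synergy import (
    DegenerateTrialError,
    analyze_deviations,
    build_jacobian,
    msd,
    null_space_basis,
    project,
    segment_synergy,
    synergy_index,
)
from ucmbalance.synthetic_data import SynthScenario, generate_deviations

from conftest import random_model


def finite_difference_jacobian(model, h=1e-6):
    """Independent oracle: numerically differentiate the whole-body xCoM
    (mass-weighted sum of reconstructed absolutes) w.r.t. each chain
    variable."""
    out = np.empty(14)
    for j in range(14):
        plus = np.zeros((1, 14, 2))
        plus[0, j, 0] = h
        minus = -plus
        f = lambda r: float(
            model.mass_fractions
            @ reconstruct(RelativeXcom(irxcom=r, model=model))[0, :, 0]
        )
        out[j] = (f(plus) - f(minus)) / (2 * h)
    return out


class TestJacobian:
    def test_matches_finite_difference_oracle_on_random_tables(self, model, rng):
        for _ in range(20):
            m = random_model(rng, model)
            jac = build_jacobian(m)
            np.testing.assert_allclose(
                jac, finite_difference_jacobian(m), atol=1e-8
            )
            assert abs(jac[m.index("trunk")] - 1.0) <= 1e-12

    def test_leaf_entry_is_own_mass_fraction(self, model):
        jac = build_jacobian(model)
        assert jac[model.index("L_hand")] == pytest.approx(
            model.mass_fraction("L_hand"), abs=1e-15
        )

    def test_upper_arm_entry_sums_distal_arm(self, model):
        jac = build_jacobian(model)
        expected = sum(
            model.mass_fraction(s) for s in ("R_upper_arm", "R_forearm", "R_hand")
        )
        assert jac[model.index("R_upper_arm")] == pytest.approx(expected, abs=1e-15)


class TestNullSpace:
    def test_defining_properties(self, jacobian):
        eps = null_space_basis(jacobian)
        assert eps.shape == (14, 13)
        assert np.max(np.abs(jacobian @ eps)) <= 1e-12
        assert np.max(np.abs(eps.T @ eps - np.eye(13))) <= 1e-12

    def test_canonical_axis_jacobian(self):
        j = np.zeros(14)
        j[0] = 1.0
        eps = null_space_basis(j)
        # the first coordinate never appears in the null space
        assert np.max(np.abs(eps[0, :])) <= 1e-12

    def test_projector_equals_rank_one_complement(self, jacobian):
        eps = null_space_basis(jacobian)
        closed = np.eye(14) - np.outer(jacobian, jacobian) / (jacobian @ jacobian)
        assert np.max(np.abs(eps @ eps.T - closed)) <= 1e-12

    def test_zero_jacobian_fatal(self):
        with pytest.raises(ValueError):
            null_space_basis(np.zeros(14))


class TestProjection:
    def test_null_space_vectors_are_fixed_points(self, jacobian, rng):
        eps = null_space_basis(jacobian)
        dev = rng.normal(size=(30, 13)) @ eps.T
        tir, tr = project(dev, eps)
        np.testing.assert_allclose(tir, dev, atol=1e-12)
        np.testing.assert_allclose(tr, 0.0, atol=1e-12)

    def test_range_space_vectors_project_to_zero_tir(self, jacobian, rng):
        dev = rng.normal(size=(30, 1)) * jacobian
        tir, tr = project(dev, null_space_basis(jacobian))
        np.testing.assert_allclose(tir, 0.0, atol=1e-12)
        np.testing.assert_allclose(tr, dev, atol=1e-12)

    def test_matches_least_squares_oracle(self, jacobian, rng):
        """tir from the basis equals the least-squares projection onto the
        null-space columns solved independently."""
        eps = null_space_basis(jacobian)
        dev = rng.normal(size=(25, 14))
        tir, _ = project(dev, eps)
        coef, *_ = np.linalg.lstsq(eps, dev.T, rcond=None)
        np.testing.assert_allclose(tir, (eps @ coef).T, atol=1e-10)

    def test_two_basis_constructions_agree(self, jacobian, rng):
        """The projector, not the basis, is the object: an independently
        built (Gram-Schmidt) orthonormal null-space basis gives identical
        components."""
        eps_svd = null_space_basis(jacobian)
        jhat = jacobian / np.linalg.norm(jacobian)
        raw = rng.normal(size=(14, 13))
        raw -= np.outer(jhat, jhat @ raw)
        eps_gs, _ = np.linalg.qr(raw)
        assert np.max(np.abs(jacobian @ eps_gs)) <= 1e-10
        dev = rng.normal(size=(40, 14))
        tir1, tr1 = project(dev, eps_svd)
        tir2, tr2 = project(dev, eps_gs)
        np.testing.assert_allclose(tir1, tir2, atol=1e-10)
        np.testing.assert_allclose(tr1, tr2, atol=1e-10)

    def test_conservation_and_orthogonality(self, jacobian, rng):
        eps = null_space_basis(jacobian)
        dev = rng.normal(size=(1000, 14))
        tir, tr = project(dev, eps)
        np.testing.assert_allclose(tir + tr, dev, atol=1e-12)
        assert np.max(np.abs(np.einsum("ti,ti->t", tir, tr))) <= 1e-12
        _, msd_tir = msd(tir)
        _, msd_tr = msd(tr)
        total = np.mean(np.sum(dev**2, axis=1))
        assert abs(msd_tir + msd_tr - total) / total <= 1e-10

    def test_tir_component_leaves_whole_body_xcom_unchanged(self, model, jacobian, rng):
        """Replaying only the task-irrelevant component through the task
        equation must not move the whole-body xCoM."""
        eps = null_space_basis(jacobian)
        dev = rng.normal(size=(200, 14))
        tir, _ = project(dev, eps)
        rel = RelativeXcom(irxcom=tir[:, :, None], model=model)
        xcom = np.einsum("i,tik->tk", model.mass_fractions, reconstruct(rel))
        assert np.max(np.abs(xcom)) <= 1e-10


class TestMsd:
    def test_constant_component(self):
        per, total = msd(np.full((7, 14), 0.3))
        np.testing.assert_allclose(per, 0.09, atol=1e-14)
        assert total == pytest.approx(14 * 0.09)

    def test_alternating_sign_has_constant_square(self):
        comp = np.tile([[0.2], [-0.2]], (5, 14))
        per, _ = msd(comp)
        np.testing.assert_allclose(per, 0.04, atol=1e-14)

    def test_empty_window_fatal(self):
        with pytest.raises(ValueError):
            msd(np.empty((0, 14)))


class TestSynergyIndex:
    @pytest.mark.parametrize(
        "tir,tr,expected",
        [
            (1.0, 0.0, 1 / 13),     # pure null-space deviation
            (0.0, 1.0, -1.0),       # pure range-space deviation
            (13.0, 1.0, 0.0),       # balance point
        ],
    )
    def test_closed_forms(self, tir, tr, expected):
        assert synergy_index(tir, tr) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_trial_fatal(self):
        with pytest.raises(DegenerateTrialError):
            synergy_index(0.0, 0.0)

    @given(
        tir=st.floats(0.0, 1e3, allow_nan=False),
        tr=st.floats(0.0, 1e3, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds(self, tir, tr):
        if tir + tr <= 0:
            return
        s = synergy_index(tir, tr)
        assert -1.0 - 1e-12 <= s <= 1 / 13 + 1e-12

    def test_segment_synergy_symmetry_and_bounds(self, rng):
        a = rng.uniform(0, 1, 14)
        np.testing.assert_allclose(segment_synergy(a, a), 0.0, atol=1e-14)
        np.testing.assert_allclose(segment_synergy(a, np.zeros(14)), 1.0)
        np.testing.assert_allclose(segment_synergy(np.zeros(14), a), -1.0)
        vals = segment_synergy(rng.uniform(0, 1, 14), rng.uniform(0, 1, 14))
        assert np.all(vals >= -1) and np.all(vals <= 1)

    def test_zero_denominator_segment_flagged_nan(self):
        a = np.ones(14)
        b = np.ones(14)
        a[3] = b[3] = 0.0
        vals = segment_synergy(a, b)
        assert np.isnan(vals[3])
        assert np.isfinite(np.delete(vals, 3)).all()


class TestParameterRecovery:
    def test_generated_variance_structure_is_recovered(self, jacobian):
        """MSDs estimated from deviations with known subspace content match
        13*sigma_tir^2 and sigma_tr^2 within Monte-Carlo error."""
        sigma_tir, sigma_tr = 0.02, 0.01
        scenario = SynthScenario(
            seed=42, n_samples=10_000, sigma_tir=sigma_tir, sigma_tr=sigma_tr
        )
        dev, truth = generate_deviations(scenario, jacobian)
        res = analyze_deviations(dev, jacobian)
        expect_tir = 13 * sigma_tir**2
        expect_tr = sigma_tr**2
        assert abs(res.msd_tir - expect_tir) / expect_tir < 0.05
        assert abs(res.msd_tr - expect_tr) / expect_tr < 0.05
        expect_syn = (sigma_tir**2 - sigma_tr**2) / (13 * sigma_tir**2 + sigma_tr**2)
        assert abs(res.syn - expect_syn) < 0.005
        # the estimated split matches the generator's exact bookkeeping
        np.testing.assert_allclose(res.tir, truth.tir, atol=1e-12)
        np.testing.assert_allclose(res.tr, truth.tr, atol=1e-12)
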