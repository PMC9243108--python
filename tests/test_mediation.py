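"""Phase-distance mediation: proximity metric, path fitting, surrogate and
group inference, and the rank-based supplement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from corticothal.exceptions import NumericalError, ValidationError
from corticothal.mediation import (
    check_mediator_direction,
    fit_paths,
    group_sign_flip_test,
    indirect_effect,
    mediation_surrogate,
    partial_spearman,
    phase_proximity,
    reference_phase_from_hits,
)
from corticothal.synthetic import MediationStrengths, SimulationConfig, make_behavior


class TestPhaseProximity:
    def test_analytic_values(self):
        assert np.isclose(phase_proximity(0.7, 0.7), 1.0)
        assert np.isclose(phase_proximity(0.7 + np.pi, 0.7), 0.0, atol=1e-12)
        assert np.isclose(phase_proximity(0.7 + np.pi / 2, 0.7), np.sqrt(2) / 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(-np.pi, np.pi, allow_nan=False),
        st.floats(-np.pi, np.pi, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_symmetric_and_rotation_invariant(self, a, b, rot):
        assert np.isclose(phase_proximity(a, b), phase_proximity(b, a))
        assert np.isclose(
            phase_proximity(a + rot, b + rot), phase_proximity(a, b), atol=1e-9
        )
        assert 0.0 <= phase_proximity(a, b) <= 1.0 + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            phase_proximity(np.nan, 0.0)


class TestReferencePhase:
    def test_constant_hits(self):
        out = np.array([1, 1, 0, 1])
        ph = np.array([0.5, 0.5, 2.0, 0.5])
        assert np.isclose(reference_phase_from_hits(ph, out), 0.5)

    def test_symmetric_pair_averages(self):
        ph = np.array([0.8 - 0.3, 0.8 + 0.3])
        assert np.isclose(reference_phase_from_hits(ph, np.array([1, 1])), 0.8)

    def test_von_mises_concentration_recovery(self):
        rng = np.random.default_rng(0)
        ph = rng.vonmises(1.2, 8.0, 100)
        ref = reference_phase_from_hits(ph, np.ones(100))
        assert abs(np.angle(np.exp(1j * (ref - 1.2)))) < 0.2

    def test_too_few_hits(self):
        with pytest.raises(ValidationError):
            reference_phase_from_hits(np.array([0.1, 0.2]), np.array([1, 0]))


class TestIndirectEffect:
    def test_closed_form_values(self):
        assert indirect_effect(0.0, 3.7) == 0.0
        assert np.isclose(indirect_effect(2.0, 2.0), 4.0 / 3.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-20, 20, allow_nan=False), st.floats(-20, 20, allow_nan=False))
    def test_odd_and_bounded(self, ta, tb):
        ab = indirect_effect(ta, tb)
        assert np.isclose(indirect_effect(-ta, tb), -ab)
        assert np.isclose(indirect_effect(ta, -tb), -ab)
        denom = np.sqrt(ta**2 + tb**2)
        if denom > 0:
            assert abs(ab) <= abs(ta * tb) / denom + 1e-12


class TestFitPaths:
    def test_identity_between_fields(self):
        rng = np.random.default_rng(1)
        cfg = SimulationConfig(mediation=MediationStrengths(1.0, 1.0, 0.3))
        x = rng.uniform(0, 1, 300)
        m, y = make_behavior(x, cfg, rng=rng)
        p = fit_paths(x, m, y)
        assert np.isclose(p.ab, indirect_effect(p.t_a, p.t_b))
        assert abs(p.ab) < min(abs(p.t_a), abs(p.t_b)) + 1.0

    def test_input_validation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 50)
        m = rng.uniform(0, 1, 50)
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(ValidationError):
            fit_paths(x[:10], m[:10], y[:10])  # too few trials
        with pytest.raises(ValidationError):
            fit_paths(np.full(50, 0.5), m, y)  # constant predictor
        with pytest.raises(ValidationError):
            fit_paths(x, m, np.ones(50))  # one outcome class

    def test_perfect_separation_flagged(self):
        x = np.linspace(0, 1, 60)
        m = np.linspace(0, 1, 60)
        y = (x > 0.5).astype(int)
        with pytest.raises(NumericalError):
            fit_paths(x, m, y)


class TestMediationSurrogate:
    def test_planted_mediation_detected(self):
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(mediation=MediationStrengths(1.5, 1.5, 0.0))
        x = rng.uniform(0, 1, 300)
        m, y = make_behavior(x, cfg, rng=rng)
        inf = mediation_surrogate(x, m, y, n_perm=200, seed=0)
        assert inf.z_ab > 2.0
        assert inf.p_ab < 0.05

    def test_null_chain_calibrated(self):
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(mediation=MediationStrengths(0.0, 0.0, 0.0))
        zs = []
        for _ in range(12):
            x = rng.uniform(0, 1, 150)
            m, y = make_behavior(x, cfg, rng=rng)
            zs.append(mediation_surrogate(x, m, y, n_perm=120, seed=1).z_ab)
        assert abs(np.mean(zs)) < 1.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(mediation=MediationStrengths(1.0, 1.0, 0.2))
        x = rng.uniform(0, 1, 200)
        m, y = make_behavior(x, cfg, rng=rng)
        a = mediation_surrogate(x, m, y, n_perm=120, seed=7)
        b = mediation_surrogate(x, m, y, n_perm=120, seed=7)
        assert a.z_ab == b.z_ab
        assert a.z_total_minus_direct == b.z_total_minus_direct

    def test_min_permutations_enforced(self):
        with pytest.raises(ValidationError):
            mediation_surrogate(
                np.linspace(0, 1, 30), np.linspace(0, 1, 30),
                np.tile([0, 1], 15), n_perm=50, seed=0,
            )


class TestGroupSignFlip:
    def test_six_units_enumerate_64(self):
        res = group_sign_flip_test(np.array([1.0, 2, 3, 1, 2, 3]))
        assert res["n_perm"] == 64

    def test_equal_positive_values_smallest_p(self):
        res = group_sign_flip_test(np.full(6, 2.5))
        assert res["p"] == 1.0 / 64.0

    def test_symmetric_values_near_half(self):
        res = group_sign_flip_test(np.array([1.0, -1, 2, -2, 3, -3]))
        assert 0.3 < res["p"] < 0.7

    def test_twelve_units_enumerate_4096(self):
        res = group_sign_flip_test(np.ones(12) + np.arange(12) * 0.1)
        assert res["n_perm"] == 4096

    def test_sampled_mode_above_twelve(self):
        rng = np.random.default_rng(0)
        res = group_sign_flip_test(rng.standard_normal(20) + 1, n_perm=500, seed=1)
        assert res["n_perm"] == 500

    def test_validation(self):
        with pytest.raises(ValidationError):
            group_sign_flip_test(np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            group_sign_flip_test(np.zeros(6))


class TestPartialSpearman:
    def test_independent_mediator_leaves_rho_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 400)
        y = x + 0.3 * rng.standard_normal(400)
        m = rng.uniform(0, 1, 400)
        res = partial_spearman(x, m, y)
        assert abs(res["rho_XY_given_M"] - res["rho_XY"]) < 0.05

    def test_monotone_relation_survives_noise_mediator(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 200)
        # exactly monotone Y makes the rank covariance singular; marginal
        # rho is 1, and a near-monotone Y keeps the partial near 1
        assert np.isclose(
            float(stats.spearmanr(x, x**3).statistic), 1.0
        )
        y = x + 0.05 * rng.standard_normal(200)
        res = partial_spearman(x, rng.uniform(0, 1, 200), y)
        assert res["rho_XY"] > 0.95
        assert res["rho_XY_given_M"] > 0.9

    def test_planted_chain_attenuates_partial(self):
        rng = np.random.default_rng(8)
        attenuated = 0
        for _ in range(20):
            x = rng.uniform(0, 1, 300)
            m = x + 0.4 * rng.standard_normal(300)
            y = (stats.norm.cdf(2.0 * (m - 0.5)) > rng.random(300)).astype(float)
            res = partial_spearman(x, m, y)
            attenuated += abs(res["rho_XY_given_M"]) < abs(res["rho_XY"])
        assert attenuated >= 18

    def test_matches_rank_pearson_formula(self):
        rng = np.random.default_rng(9)
        x, m = rng.uniform(0, 1, (2, 80))
        y = x + 0.5 * m + 0.2 * rng.standard_normal(80)
        res = partial_spearman(x, m, y)
        rx = stats.rankdata(x)
        rm = stats.rankdata(m)
        ry = stats.rankdata(y)
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xm = np.corrcoef(rx, rm)[0, 1]
        r_ym = np.corrcoef(ry, rm)[0, 1]
        expected = (r_xy - r_xm * r_ym) / np.sqrt((1 - r_xm**2) * (1 - r_ym**2))
        assert np.isclose(res["rho_XY_given_M"], expected, atol=1e-10)

    def test_validation(self):
        with pytest.raises(ValidationError):
            partial_spearman(np.ones(30), np.linspace(0, 1, 30), np.linspace(0, 1, 30))


def test_mediator_direction_guard():
    check_mediator_direction(0.2)  # cortex leads: fine
    with pytest.raises(ValidationError):
        check_mediator_direction(-0.2)
    with pytest.warns(UserWarning):
        check_mediator_direction(-0.2, override=True)
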