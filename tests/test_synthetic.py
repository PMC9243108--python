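"""Generator and paradigm-simulator behavior: reproducibility, planted
structure, the behavioral chain, and the adaptive staircase."""

import numpy as np
import pytest
from scipy import stats

from corticothal.data import EpochedRecording
from corticothal.exceptions import ValidationError
from corticothal.phase_stats import itpc, pbi
from corticothal.spectral import morlet_tfr
from corticothal.synthetic import (
    MediationStrengths,
    SimulationConfig,
    frame_duration_ms,
    logistic_observer,
    make_behavior,
    simulate_epochs,
    simulate_staircase,
    vonmises_kappa_for_resultant,
)


def _ref_phases(rec, freq=10.0, t_ref=-0.4):
    spec = morlet_tfr(rec, freqs=np.array([freq]), times=np.array([t_ref]))
    return spec.phase[:, :, 0, 0]


class TestSimulateEpochs:
    def test_identical_seed_bit_identical(self):
        cfg = SimulationConfig(n_trials=30, seed=11)
        a, b = simulate_epochs(cfg), simulate_epochs(cfg)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.outcome, b.outcome)

    def test_different_seed_differs(self):
        a = simulate_epochs(SimulationConfig(n_trials=30, seed=1))
        b = simulate_epochs(SimulationConfig(n_trials=30, seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_planted_opposition_hits_cluster_at_optimum(self):
        cfg = SimulationConfig(
            n_trials=200, noise_amp=0.0, phase_opposition_strength=8.0, seed=1
        )
        rec = simulate_epochs(cfg)
        ph = _ref_phases(rec)[:, 0]
        hits = rec.outcome == 1
        assert itpc(ph[hits]) > 0.9
        mean_phase = np.angle(np.exp(1j * ph[hits]).mean())
        assert abs(mean_phase - cfg.optimal_phase) < 0.2
        # misses at the antipode -> positive bifurcation; the 71/29 trial
        # imbalance keeps ITPC_combined well above zero, bounding PBI below
        # the balanced-design value of ~(1 - |2p - 1|)^2
        assert pbi(ph[hits], ph[~hits]) > 0.1

    def test_pure_delayed_copy_phase_difference(self):
        cfg = SimulationConfig(
            n_trials=5, noise_amp=0.0, coupling_gain=1.0,
            lag_cortex_to_thal=0.02, seed=2,
        )
        rec = simulate_epochs(cfg)
        shift = int(round(0.02 * cfg.fs))
        assert np.allclose(rec.data[:, 1], np.roll(rec.data[:, 0], shift, axis=-1))
        spec = morlet_tfr(
            rec, freqs=np.array([10.0]), times=np.arange(-0.7, 0.0, 0.05)
        )
        d = np.angle(np.exp(1j * (spec.phase[:, 0] - spec.phase[:, 1])))
        assert np.allclose(d, 2 * np.pi * 10.0 * 0.02, atol=0.02)

    def test_no_structure_when_kappa_zero_and_uncoupled(self):
        cfg = SimulationConfig(
            n_trials=150, phase_opposition_strength=0.0, coupling_gain=0.0, seed=3
        )
        rec = simulate_epochs(cfg)
        ph = _ref_phases(rec)
        hits = rec.outcome == 1
        # no condition-wise clustering beyond sampling noise (Rayleigh scale)
        for ch in (0, 1):
            assert itpc(ph[hits, ch]) < 3.0 / np.sqrt(hits.sum())
        assert abs(pbi(ph[hits, 0], ph[~hits, 0])) < 0.05

    def test_mediation_mode_plants_bifurcation_and_coupling(self):
        cfg = SimulationConfig(
            n_trials=300, outcome_mode="mediation", coupling_gain=0.8,
            coupling_gain_miss=0.0, seed=4,
        )
        rec = simulate_epochs(cfg)
        ph = _ref_phases(rec)
        hits = rec.outcome == 1
        assert pbi(ph[hits, 0], ph[~hits, 0]) > 0.01
        assert pbi(ph[hits, 1], ph[~hits, 1]) > 0.01
        assert itpc(ph[:, 0] - ph[:, 1]) > 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(fs=15.0),  # Nyquist violation at 10 Hz
            dict(n_trials=0),
            dict(phase_opposition_strength=-1.0),
            dict(coupling_gain=1.5),
            dict(hit_rate_target=0.0),
            dict(outcome_mode="nonsense"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            simulate_epochs(SimulationConfig(**kwargs))

    def test_kappa_for_resultant_inverts(self):
        for r in (0.0, 0.3, 0.8, 0.95):
            k = vonmises_kappa_for_resultant(r)
            if r == 0:
                assert k == 0
            else:
                from scipy.special import i0, i1

                assert abs(i1(k) / i0(k) - r) < 1e-8


class TestMakeBehavior:
    def test_hit_rate_matches_target(self):
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(hit_rate_target=0.71)
        x = rng.uniform(0, 1, 4000)
        _, y = make_behavior(x, cfg, rng=rng)
        se = np.sqrt(0.71 * 0.29 / 4000)
        assert abs(y.mean() - 0.71) < 3 * se

    def test_null_strengths_give_null_paths(self):
        from corticothal.mediation import fit_paths

        rng = np.random.default_rng(5)
        cfg = SimulationConfig(mediation=MediationStrengths(0.0, 0.0, 0.0))
        hits = []
        for _ in range(60):
            x = rng.uniform(0, 1, 120)
            m, y = make_behavior(x, cfg, rng=rng)
            p = fit_paths(x, m, y)
            hits.append([abs(p.t_a) > 2, abs(p.t_b) > 2, abs(p.t_cprime) > 2])
        rates = np.mean(hits, axis=0)
        assert np.all(rates < 0.15)  # ~5% nominal, binomial slack at 60 reps

    def test_strong_chain_recovered(self):
        from corticothal.mediation import fit_paths

        rng = np.random.default_rng(6)
        cfg = SimulationConfig(mediation=MediationStrengths(1.5, 1.5, 0.0))
        x = rng.uniform(0, 1, 1000)
        m, y = make_behavior(x, cfg, rng=rng)
        p = fit_paths(x, m, y)
        assert p.t_a > 5 and p.t_b > 3
        assert abs(p.t_cprime) < 3
        assert p.ab > 2

    def test_proximity_bounds_enforced(self):
        with pytest.raises(ValidationError):
            make_behavior(np.array([0.2, 1.4]), SimulationConfig())


class TestStaircase:
    def test_perfect_observer_marches_to_floor(self):
        trace = simulate_staircase(lambda level: 1.0, 500, seed=0)
        assert trace.level.min() == 0.0
        assert trace.level[-1] == 0.0
        assert trace.asymptote_estimate == 1.0

    def test_two_up_one_down_converges_near_707(self):
        trace = simulate_staircase(logistic_observer(), 4000, seed=1)
        assert abs(trace.asymptote_estimate - np.sqrt(0.5)) < 0.02

    def test_asymptote_stable_across_seeds(self):
        est = [
            simulate_staircase(logistic_observer(), 4000, seed=s).asymptote_estimate
            for s in range(5)
        ]
        assert max(est) - min(est) < 0.04
        assert all(abs(e - np.sqrt(0.5)) < 0.02 for e in est)

    def test_level_changes_follow_rule(self):
        trace = simulate_staircase(logistic_observer(), 300, seed=2, step=1.0)
        level, correct = trace.level, trace.correct
        run = 0
        for i in range(len(level) - 1):
            delta = level[i + 1] - level[i]
            if correct[i]:
                run += 1
                if run == 2:
                    assert delta == -1.0 or (level[i] == 0.0 and delta == 0.0)
                    run = 0
                else:
                    assert delta == 0.0
            else:
                assert delta == 1.0
                run = 0
        assert level.min() >= 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            simulate_staircase(logistic_observer(), 50)  # too few trials
        with pytest.raises(ValidationError):
            simulate_staircase(logistic_observer(), 500, step=0.0)

    def test_non_monotone_observer_warns(self):
        with pytest.warns(UserWarning):
            simulate_staircase(lambda v: 0.9 - 0.05 * v, 200, seed=0)


def test_frame_duration_matches_display_refresh():
    assert round(frame_duration_ms(60.0), 1) == 16.7
    assert round(frame_duration_ms(120.0), 1) == 8.3
    with pytest.raises(ValidationError):
        frame_duration_ms(0.0)


def test_recording_container_validation(time_axis):
    t, fs = time_axis
    good = np.zeros((4, 1, t.size))
    with pytest.raises(ValidationError):
        EpochedRecording(good, t[:-1], fs, ["a"], np.ones(4))
    with pytest.raises(ValidationError):
        EpochedRecording(good, t, fs, ["a"], np.ones(3))
    bad = good.copy()
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValidationError):
        EpochedRecording(bad, t, fs, ["a"], np.ones(4))
    with pytest.raises(ValidationError):
        EpochedRecording(good, t, fs, ["a"], np.array([0, 1, 2, 1]))
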