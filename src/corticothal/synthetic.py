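"""Synthetic two-region oscillatory epochs and a behavioral-paradigm simulator.

The generator plants the three structures the analysis pipeline is built to
recover:

* **phase opposition** — pre-stimulus phase at a reference time clusters at a
  reference ("optimal") angle for hits and at the antipode for misses
  (von Mises with concentration ``kappa``);
* **directed lag** — the thalamic channel receives a time-delayed copy of the
  shared cortical signal (oscillation plus 1/f noise), so the cortical channel
  temporally leads;
* **a mediation chain** — cortical phase proximity drives thalamic phase
  proximity drives hit probability, through an explicit latent model
  (:func:`make_behavior`).

A delayed pure sinusoid is indistinguishable from a phase-shifted one, so the
broadband 1/f noise travels through the delayed pathway as well: that is what
gives the phase-slope ground truth a non-zero slope across frequencies.

Also houses the adaptive 2-up-1-down staircase simulator used to emulate the
behavioral calibration procedure (two consecutive correct responses make the
task harder, one error makes it easier; converges on ~70.7% correct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, i0, i1, ndtr

from .data import EpochedRecording
from .exceptions import ValidationError


@dataclass
class MediationStrengths:
    """Standardized path weights of the generative mediation chain.

    ``a_strength`` scales the latent linear path X -> M, ``b_strength`` and
    ``c_strength`` enter the logistic outcome model on standardized X and M.
    """

    a_strength: float = 0.8
    b_strength: float = 1.5
    c_strength: float = 0.3


@dataclass
class SimulationConfig:
    """Parameters of the two-channel epoch generator.

    Defaults are the package's reference study conditions: 300 trials of 4 s
    epochs (stimulus at 0 s) sampled at 250 Hz, 10 Hz oscillations of unit
    amplitude in both channels embedded in 1/f noise of matched standard
    deviation, phase opposition planted at -400 ms with concentration
    ``kappa = 8``, a 20 ms cortex-to-thalamus delay with coupling gain 0.8,
    and a ~71% hit rate.
    """

    n_trials: int = 300
    fs: float = 250.0
    t_start: float = -2.0
    t_end: float = 2.0
    osc_freq_cortex: float = 10.0
    osc_freq_thal: float = 10.0
    osc_amp: float = 1.0
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    phase_opposition_strength: float = 8.0  # von Mises kappa
    optimal_phase: float = 0.0
    reference_time: float = -0.4
    lag_cortex_to_thal: float = 0.020
    coupling_gain: float = 0.8
    coupling_gain_miss: float = None  # mediation mode only; None -> same as hits
    mediation: MediationStrengths = field(default_factory=MediationStrengths)
    hit_rate_target: float = 0.71
    outcome_mode: str = "condition"  # "condition" | "mediation"
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        nyq = self.fs / 2.0
        if max(self.osc_freq_cortex, self.osc_freq_thal) >= nyq:
            raise ValidationError(
                f"oscillation frequency violates Nyquist ({nyq:g} Hz at fs={self.fs:g})"
            )
        if self.phase_opposition_strength < 0:
            raise ValidationError("phase_opposition_strength (kappa) must be >= 0")
        if not 0.0 <= self.coupling_gain <= 1.0:
            raise ValidationError("coupling_gain must lie in [0, 1]")
        if self.coupling_gain_miss is not None and not (
            0.0 <= self.coupling_gain_miss <= 1.0
        ):
            raise ValidationError("coupling_gain_miss must lie in [0, 1]")
        if not 0.0 < self.hit_rate_target < 1.0:
            raise ValidationError("hit_rate_target must lie in (0, 1)")
        if self.t_end <= self.t_start:
            raise ValidationError("t_end must exceed t_start")
        if self.outcome_mode not in ("condition", "mediation"):
            raise ValidationError(
                f"outcome_mode must be 'condition' or 'mediation', got {self.outcome_mode!r}"
            )


def _powerlaw_noise(rng, shape, exponent, fs):
    """1/f^exponent noise, unit standard deviation per trace."""
    white = rng.standard_normal(shape)
    if exponent == 0:
        out = white
    else:
        n = shape[-1]
        f = np.fft.rfftfreq(n, 1.0 / fs)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        spec = np.fft.rfft(white, axis=-1) * scale
        out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _proximity(theta, ref):
    # resultant length of the two-angle set {theta, ref}: |cos((ref - theta)/2)|
    return np.abs(np.cos((np.asarray(theta) - ref) / 2.0))


def vonmises_kappa_for_resultant(r: float) -> float:
    """Concentration kappa such that the von Mises mean resultant length is r."""
    if not 0.0 <= r < 1.0:
        if r == 1.0:
            return np.inf
        raise ValidationError("target resultant length must lie in [0, 1]")
    if r == 0.0:
        return 0.0
    return float(brentq(lambda k: i1(k) / i0(k) - r, 1e-9, 700.0))


def _draw_outcome(x, m, c_strength, b_strength, hit_rate_target, rng):
    """Bernoulli outcomes from a logistic link on standardized X and M.

    The intercept is root-found so the mean hit probability equals
    ``hit_rate_target``.
    """

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    lin = c_strength * z(np.asarray(x, dtype=float)) + b_strength * z(
        np.asarray(m, dtype=float)
    )
    lo, hi = -30.0, 30.0

    def mean_rate(j):
        return expit(j + lin).mean() - hit_rate_target

    if mean_rate(lo) > 0 or mean_rate(hi) < 0:
        raise ValidationError(
            f"hit_rate_target={hit_rate_target} unattainable for given strengths"
        )
    j = brentq(mean_rate, lo, hi)
    return (rng.random(lin.size) < expit(j + lin)).astype(np.uint8)


def _oscillation(t, freq, phase_at_ref, reference_time, amp):
    """Sinusoid whose instantaneous phase at ``reference_time`` equals ``phase_at_ref``."""
    phi0 = np.atleast_1d(phase_at_ref) - 2 * np.pi * freq * reference_time
    return amp * np.cos(2 * np.pi * freq * t[None, :] + phi0[:, None])


def simulate_epochs(config: SimulationConfig) -> EpochedRecording:
    """Generate a two-channel epoched recording with plantable structure.

    In ``condition`` mode, outcomes are drawn first (Bernoulli at
    ``hit_rate_target``) and the cortical phase at the reference time is von
    Mises around ``optimal_phase`` for hits and the antipode for misses; the
    thalamic channel is ``coupling_gain`` x the delayed cortical signal plus
    ``(1 - coupling_gain)`` x an independent oscillation-plus-noise.

    In ``mediation`` mode, cortical phase is uniform and the mediation chain
    runs on the circle: the thalamic phase is the lagged cortical phase plus
    von Mises coupling noise (concentration chosen so the planted
    phase-difference consistency equals ``coupling_gain``), the proximities
    X and M are the distances of the two phases to their respective optima,
    and the outcome is logistic in (X, M) with weights ``c_strength`` and
    ``b_strength`` (intercept root-found to hit ``hit_rate_target``). The
    delayed broadband pathway is gated per trial (``coupling_gain`` for hits,
    ``coupling_gain_miss`` for misses), planting an outcome-dependent
    directed-coupling contrast. The latent-Gaussian mediator of
    :func:`make_behavior` is available as a standalone chain; inside the
    epoch generator the X -> M path strength is the phase coupling itself.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    n_samples = int(round((config.t_end - config.t_start) * config.fs)) + 1
    t = config.t_start + np.arange(n_samples) / config.fs
    shift = int(round(config.lag_cortex_to_thal * config.fs))
    kappa = config.phase_opposition_strength

    noise_cx = _powerlaw_noise(rng, (n, n_samples), config.noise_exponent, config.fs)
    noise_th = _powerlaw_noise(rng, (n, n_samples), config.noise_exponent, config.fs)

    if config.outcome_mode == "condition":
        outcome = (rng.random(n) < config.hit_rate_target).astype(np.uint8)
        mu = np.where(outcome == 1, config.optimal_phase, config.optimal_phase + np.pi)
        if kappa > 0:
            theta_cx = rng.vonmises(mu, kappa)
        else:
            theta_cx = rng.uniform(-np.pi, np.pi, n)
        cortex = _oscillation(
            t, config.osc_freq_cortex, theta_cx, config.reference_time, config.osc_amp
        )
        if config.noise_amp > 0:
            cortex = cortex + config.noise_amp * noise_cx
        indep = _oscillation(
            t,
            config.osc_freq_thal,
            rng.uniform(-np.pi, np.pi, n),
            config.reference_time,
            config.osc_amp,
        )
        if config.noise_amp > 0:
            indep = indep + config.noise_amp * noise_th
        g = config.coupling_gain
        thal = g * np.roll(cortex, shift, axis=-1) + (1.0 - g) * indep
    else:
        # The mediator must live on the circle: the thalamic phase is the
        # lagged cortical phase plus von Mises coupling noise whose
        # concentration is set so the planted phase-difference consistency
        # (ISPC) equals coupling_gain. Hits and misses then cluster at
        # antipodal angles in *both* channels, and the X -> M path is the
        # phase coupling itself.
        theta_cx = rng.uniform(-np.pi, np.pi, n)
        lag_phase = 2 * np.pi * config.osc_freq_thal * config.lag_cortex_to_thal
        thal_opt = config.optimal_phase - lag_phase
        kappa_c = vonmises_kappa_for_resultant(config.coupling_gain)
        if kappa_c > 0:
            zeta = rng.vonmises(0.0, kappa_c, n)
        else:
            zeta = rng.uniform(-np.pi, np.pi, n)
        theta_th = theta_cx - lag_phase + zeta
        x = _proximity(theta_cx, config.optimal_phase)
        m = _proximity(theta_th, thal_opt)
        outcome = _draw_outcome(
            x, m, config.mediation.c_strength, config.mediation.b_strength,
            config.hit_rate_target, rng,
        )
        cortex = _oscillation(
            t, config.osc_freq_cortex, theta_cx, config.reference_time, config.osc_amp
        )
        thal = _oscillation(
            t, config.osc_freq_thal, theta_th, config.reference_time, config.osc_amp
        )
        if config.noise_amp > 0:
            g_miss = (
                config.coupling_gain
                if config.coupling_gain_miss is None
                else config.coupling_gain_miss
            )
            g_r = np.where(outcome == 1, config.coupling_gain, g_miss)[:, None]
            cortex = cortex + config.noise_amp * noise_cx
            thal = thal + config.noise_amp * (
                g_r * np.roll(noise_cx, shift, axis=-1)
                + np.sqrt(1.0 - g_r**2) * noise_th
            )

    data = np.stack([cortex, thal], axis=1)
    return EpochedRecording(
        data=data,
        time=t,
        fs=config.fs,
        channel_labels=["mPFC", "MD"],
        outcome=outcome,
    )


def make_behavior(phase_proximity_cortex, config: SimulationConfig, rng=None):
    """Draw thalamic phase proximity and outcomes through the mediation chain.

    ``M`` is a monotone probit squash of ``a_strength * z(X) + N(0, 1)`` into
    [0, 1]; ``P(hit) = logistic(j + c_strength * z(X) + b_strength * z(M))``
    with the intercept ``j`` root-found so the mean hit probability matches
    ``hit_rate_target``. Returns ``(M, Y)``.
    """
    x = np.asarray(phase_proximity_cortex, dtype=float)
    if x.min() < 0 or x.max() > 1:
        raise ValidationError("phase proximities must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    med = config.mediation
    sd_x = x.std()
    zx = (x - x.mean()) / sd_x if sd_x > 0 else np.zeros_like(x)
    latent = med.a_strength * zx + rng.standard_normal(x.size)
    m = ndtr(latent / np.sqrt(1.0 + med.a_strength**2))
    y = _draw_outcome(x, m, med.c_strength, med.b_strength, config.hit_rate_target, rng)
    return m, y


# ---------------------------------------------------------------------------
# Behavioral paradigm: adaptive staircase and frame arithmetic
# ---------------------------------------------------------------------------


@dataclass
class StaircaseTrace:
    """Trial-by-trial record of an n-up-1-down adaptive staircase.

    ``rule = (k, m)``: k consecutive correct responses lower the stimulus
    level by ``step`` (harder), m consecutive errors raise it (easier).
    ``asymptote_estimate`` is the proportion correct over the final half of
    trials (burn-in excluded).
    """

    level: np.ndarray
    correct: np.ndarray
    rule: tuple = (2, 1)
    step: float = 1.0
    asymptote_estimate: float = float("nan")

    @property
    def n_trials(self) -> int:
        return self.level.size


def logistic_observer(midpoint: float = 5.0, slope: float = 1.5, chance: float = 0.5):
    """P(correct | level): logistic rising from ``chance`` to ceiling 1.0.

    ``level`` is the blank-interval duration in frames; longer blanks give the
    observer more time, so performance increases monotonically with level.
    """

    def p_correct(level):
        return chance + (1.0 - chance) * expit((level - midpoint) / slope)

    return p_correct


def simulate_staircase(
    observer_psychometric,
    n_trials: int,
    rule: tuple = (2, 1),
    step: float = 1.0,
    start_level: float = 10.0,
    seed: int = 0,
) -> StaircaseTrace:
    """Run an adaptive k-up-m-down staircase against a stochastic observer.

    With the default (2, 1) rule the level converges on the point where
    P(correct)^2 = 1/2, i.e. ~70.7% correct. The level floors at 0 (below one
    frame the blank screen is simply omitted).
    """
    if n_trials < 100:
        raise ValidationError("n_trials must be >= 100 for a meaningful staircase")
    if step <= 0:
        raise ValidationError("step must be > 0")
    k_down, m_up = int(rule[0]), int(rule[1])
    if k_down < 1 or m_up < 1:
        raise ValidationError("rule counts must be >= 1")
    probe = np.linspace(0.0, max(2.0 * start_level, 1.0), 25)
    p_probe = np.asarray([observer_psychometric(v) for v in probe], dtype=float)
    if np.any(np.diff(p_probe) < -1e-9):
        warnings.warn(
            "observer psychometric function is not monotone increasing in level",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    levels = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    level = float(start_level)
    run_correct = 0
    run_error = 0
    for i in range(n_trials):
        levels[i] = level
        c = rng.random() < observer_psychometric(level)
        correct[i] = c
        if c:
            run_correct += 1
            run_error = 0
            if run_correct >= k_down:
                level = max(0.0, level - step)
                run_correct = 0
        else:
            run_error += 1
            run_correct = 0
            if run_error >= m_up:
                level = level + step
                run_error = 0
    tail = correct[n_trials // 2 :]
    return StaircaseTrace(
        level=levels,
        correct=correct,
        rule=(k_down, m_up),
        step=step,
        asymptote_estimate=float(tail.mean()),
    )


def frame_duration_ms(refresh_rate_hz: float) -> float:
    """Duration of a single display frame in milliseconds (e.g. 60 Hz -> 16.7 ms)."""
    if refresh_rate_hz <= 0:
        raise ValidationError("refresh rate must be positive")
    return 1000.0 / refresh_rate_hz
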