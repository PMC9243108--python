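"""Inter-trial phase clustering, phase bifurcation, and circular-shift surrogates.

ITPC (phase-locking value) is the length of the mean resultant vector of
per-trial phase angles, ``|n^-1 sum_r exp(i k_r)|``. The phase bifurcation
index contrasts the clustering of hits and misses against their union::

    PBI = (ITPC_hits - ITPC_combined) * (ITPC_misses - ITPC_combined)

PBI is positive when both conditions cluster, at different angles; it suffers
a trial-count bias, so inference is always against a circular-shift surrogate
distribution in which every trial's series is rotated in time by an
independent random number of samples (preserving autocorrelation and the
hit/miss imbalance) and the statistic recomputed. The observed statistic is
z-scored by the surrogate mean and SD; the surrogate's empirical one-sided
percentile is also kept, since it is exactly uniform under the null whatever
the statistic's shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import EpochedRecording
from .exceptions import NumericalError, ValidationError
from .spectral import PowerSummary, SpectralEstimate, morlet_tfr

_SD_FLOOR = 1e-12


def itpc(phases, axis=None) -> np.ndarray:
    """Inter-trial phase clustering |n^-1 sum exp(i k)| in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValidationError("itpc of an empty phase set")
    return np.abs(np.exp(1j * phases).mean(axis=axis))


def pbi(phases_hits, phases_misses, axis=None) -> np.ndarray:
    """Phase bifurcation index of two condition-wise phase sets.

    ``axis`` is the trial axis (default: flattened). Positive values indicate
    both conditions cluster at mutually opposed angles; range [-1, 1].
    """
    phases_hits = np.asarray(phases_hits, dtype=float)
    phases_misses = np.asarray(phases_misses, dtype=float)
    if phases_hits.size == 0 or phases_misses.size == 0:
        raise ValidationError("pbi requires non-empty hit and miss phase sets")
    ax = 0 if axis is None else axis
    if axis is None:
        phases_hits = phases_hits.ravel()
        phases_misses = phases_misses.ravel()
    combined = np.concatenate([phases_hits, phases_misses], axis=ax)
    i_h = itpc(phases_hits, axis=ax)
    i_m = itpc(phases_misses, axis=ax)
    i_c = itpc(combined, axis=ax)
    return (i_h - i_c) * (i_m - i_c)


def _pbi_from_unit_phasors(e, hits):
    """PBI map from unit phasors e (n_trials, ...) and a boolean hit mask."""
    n_h = int(hits.sum())
    n_m = int(e.shape[0] - n_h)
    s_h = e[hits].sum(axis=0)
    s_m = e[~hits].sum(axis=0)
    i_h = np.abs(s_h) / n_h
    i_m = np.abs(s_m) / n_m
    i_c = np.abs(s_h + s_m) / (n_h + n_m)
    return (i_h - i_c) * (i_m - i_c)


@dataclass
class SurrogateZMap:
    """Observed statistic plus its permutation null and z map.

    ``z = (observed - null_mean) / null_sd``; cells with ``null_sd`` below
    1e-12 are flagged in ``degenerate`` and carry NaN z rather than a silently
    inflated value. ``p_perm`` is the one-sided empirical percentile
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """

    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    p_perm: np.ndarray
    degenerate: np.ndarray
    n_perm: int
    seed: int


def _z_from_null(observed, null_draws, n_perm, seed) -> SurrogateZMap:
    null_mean = null_draws.mean(axis=0)
    null_sd = null_draws.std(axis=0, ddof=1)
    degenerate = null_sd < _SD_FLOOR
    if np.all(degenerate):
        raise NumericalError("surrogate distribution is degenerate everywhere (sd = 0)")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, np.nan, (observed - null_mean) / null_sd)
    p_perm = (1.0 + (null_draws >= observed[None]).sum(axis=0)) / (1.0 + n_perm)
    return SurrogateZMap(
        observed=observed, null_mean=null_mean, null_sd=null_sd, z=z,
        p_perm=p_perm, degenerate=degenerate, n_perm=n_perm, seed=seed,
    )


def circular_shift_surrogate(
    data: np.ndarray, stat_fn, n_perm: int = 1000, seed: int = 0
) -> SurrogateZMap:
    """Surrogate z map from independent per-trial circular time shifts.

    ``data`` has trials on the first axis and time on the last;
    ``stat_fn(data) -> statistic array``. Each permutation rolls every trial
    independently by a uniform random shift in [1, n_samples - 1], leaving
    condition labels (carried inside ``stat_fn``) untouched.
    """
    data = np.asarray(data)
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2 (>= 100 recommended)")
    n_trials, n_samples = data.shape[0], data.shape[-1]
    if n_samples < 2:
        raise ValidationError("need at least 2 samples to shift")
    rng = np.random.default_rng(seed)
    observed = np.asarray(stat_fn(data), dtype=float)
    col = np.arange(n_samples)
    null_draws = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        shifts = rng.integers(1, n_samples, size=n_trials)
        idx = (col[None, :] - shifts[:, None]) % n_samples
        idx = idx.reshape((n_trials,) + (1,) * (data.ndim - 2) + (n_samples,))
        shifted = np.take_along_axis(data, idx, axis=-1)
        null_draws[p] = stat_fn(shifted)
    return _z_from_null(observed, null_draws, n_perm, seed)


def pbi_map(
    spec: SpectralEstimate,
    outcome=None,
    n_perm: int = 1000,
    seed: int = 0,
    channel: int = 0,
    mode: str = "faithful",
    rec: EpochedRecording = None,
) -> SurrogateZMap:
    """Phase bifurcation z map over the (freq, time) grid for one channel.

    ``mode="faithful"`` circularly shifts the raw time series of each trial
    and re-runs the wavelet transform per permutation (requires ``rec``);
    ``mode="fast"`` instead rotates each trial's coefficients by
    ``exp(-i 2 pi f s/fs)`` for a random source-sample shift ``s``, the effect
    a circular time shift has on a narrowband analytic signal. ROI restriction
    is a group-stats concern and is not applied here.
    """
    outcome = np.asarray(spec.outcome if outcome is None else outcome)
    if outcome.shape[0] != spec.coeff.shape[0]:
        raise ValidationError("outcome length must match trial count")
    hits = outcome == 1
    n_h, n_m = int(hits.sum()), int((~hits).sum())
    if n_h < 2 or n_m < 2:
        raise ValidationError(
            f"need >= 2 trials per condition; got {n_h} hits / {n_m} misses"
        )
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    if mode == "fast":
        with np.errstate(invalid="ignore", divide="ignore"):
            e = spec.coeff[:, channel]
            e = np.where(np.abs(e) > 0, e / np.abs(e), 0.0 + 0.0j)
        observed = _pbi_from_unit_phasors(e, hits)
        null_draws = np.empty((n_perm,) + observed.shape)
        for p in range(n_perm):
            s = rng.integers(1, spec.n_source_samples, size=e.shape[0])
            rot = np.exp(
                -2j * np.pi * spec.freqs[None, :] * (s / spec.source_fs)[:, None]
            )
            null_draws[p] = _pbi_from_unit_phasors(e * rot[:, :, None], hits)
        return _z_from_null(observed, null_draws, n_perm, seed)
    if mode == "faithful":
        if rec is None:
            raise ValidationError("faithful mode requires the raw EpochedRecording")

        def stat_fn(x):
            r = EpochedRecording(
                data=x[:, None, :], time=rec.time, fs=rec.fs,
                channel_labels=["c"], outcome=outcome,
            )
            s = morlet_tfr(r, freqs=spec.freqs, times=spec.times, n_cycles=spec.n_cycles)
            e = np.exp(1j * s.phase[:, 0])
            return _pbi_from_unit_phasors(e, hits)

        return circular_shift_surrogate(
            rec.data[:, channel], stat_fn, n_perm=n_perm, seed=seed
        )
    raise ValidationError(f"mode must be 'fast' or 'faithful', got {mode!r}")


def phase_reset_test(summaries) -> dict:
    """2x2 (epoch x decomposition) repeated-measures test for phase resetting.

    ``summaries`` is a sequence of per-unit :class:`PowerSummary`. The
    interaction is the paired contrast on log power,
    ``(post - pre)_evoked - (post - pre)_total``; with two levels per factor
    the interaction F equals the squared paired t. A positive direction
    (evoked gain exceeding total gain) is the phase-reset signature.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValidationError("phase_reset_test needs >= 2 units")
    if not all(isinstance(s, PowerSummary) for s in summaries):
        raise ValidationError("summaries must be PowerSummary instances")
    contrasts = []
    for s in summaries:
        le = np.log(s.evoked["post"]) - np.log(s.evoked["pre"])
        lt = np.log(s.total["post"]) - np.log(s.total["pre"])
        contrasts.append(le - lt)
    c = np.asarray(contrasts)
    n = c.size
    sd = c.std(ddof=1)
    if sd < _SD_FLOOR:
        t_stat = 0.0 if abs(c.mean()) < _SD_FLOOR else np.inf
    else:
        t_stat = c.mean() / (sd / np.sqrt(n))
    f_stat = t_stat**2
    p = float(stats.f.sf(f_stat, 1, n - 1)) if np.isfinite(f_stat) else 0.0
    direction = "evoked_gain" if c.mean() > 0 else "total_gain"
    return {
        "F": float(f_stat), "p": p, "t": float(t_stat),
        "interaction_direction": direction, "mean_contrast": float(c.mean()),
        "df": (1, n - 1),
    }
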