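"""Undirected (ISPC) and directed (PSI) corticothalamic coupling.

Inter-site phase clustering applies the phase-locking value to the per-trial
circular phase *difference* between two channels, ``|n^-1 sum exp(i d_r)|``.
Its surrogate shuffles the trial order of one channel relative to the other,
destroying trial-wise pairing while preserving each channel's phase statistics.

The phase slope index summarizes whether the cross-channel phase difference
grows with frequency (a signature of a fixed time delay rather than volume
conduction): from Hanning-tapered per-trial FFT spectra of the pre-stimulus
window, complex coherency C(f) is estimated with trials as observations and

    psi = Im( sum_{f in band} conj(C(f)) C(f + df) )

summed over a configurable band (default 5-11 Hz, a 6 Hz bandwidth centred on
the ~8 Hz coupling peak). Positive psi means the first channel temporally
leads; psi is exactly antisymmetric under swapping the channels, and a
zero-lag (volume-conducted) copy contributes exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EpochedRecording
from .exceptions import ValidationError
from .phase_stats import SurrogateZMap, _z_from_null, itpc
from .spectral import SpectralEstimate


def ispc(phase_differences, axis=None) -> np.ndarray:
    """Inter-site phase clustering of per-trial phase differences, in [0, 1]."""
    return itpc(phase_differences, axis=axis)


def ispc_map(spec: SpectralEstimate, channel_a=0, channel_b=1) -> np.ndarray:
    """ISPC over trials at every (freq, time) cell for a channel pair."""
    d = spec.phase[:, channel_a] - spec.phase[:, channel_b]
    return ispc(d, axis=0)


def trial_shuffle_surrogate(
    data_a: np.ndarray,
    data_b: np.ndarray,
    stat_fn,
    n_perm: int = 1000,
    seed: int = 0,
) -> SurrogateZMap:
    """Surrogate z map from shuffling the trial order of ``data_a`` only.

    ``stat_fn(a, b) -> statistic array`` with trials on the first axis of both
    inputs. Mirrors shuffling one region's recordings relative to the other's.
    """
    data_a, data_b = np.asarray(data_a), np.asarray(data_b)
    if data_a.shape[0] != data_b.shape[0]:
        raise ValidationError(
            f"trial counts differ: {data_a.shape[0]} vs {data_b.shape[0]}"
        )
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    observed = np.asarray(stat_fn(data_a, data_b), dtype=float)
    null_draws = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        perm = rng.permutation(data_a.shape[0])
        null_draws[p] = stat_fn(data_a[perm], data_b)
    return _z_from_null(observed, null_draws, n_perm, seed)


def ispc_zmap(
    spec: SpectralEstimate,
    channel_a=0,
    channel_b=1,
    n_perm: int = 1000,
    seed: int = 0,
) -> SurrogateZMap:
    """ISPC z map against the trial-shuffle null for one channel pair."""
    pa = spec.phase[:, channel_a]
    pb = spec.phase[:, channel_b]
    return trial_shuffle_surrogate(
        pa, pb, lambda a, b: ispc(a - b, axis=0), n_perm=n_perm, seed=seed
    )


@dataclass
class LagSummary:
    """Group summary of per-unit mean phase lags (unweighted circular mean)."""

    mean_lag: float
    resultant_length: float
    per_unit_lags: np.ndarray


def phase_lag_summary(per_unit_phase_differences) -> LagSummary:
    """Circular mean lag per unit, then an unweighted circular mean across units.

    Input: an iterable of per-trial phase-difference arrays, one per unit.
    Each unit contributes only its mean lag angle — not its resultant length —
    to the group average, so tightly and loosely clustered units weigh equally.
    """
    units = [np.asarray(d, dtype=float).ravel() for d in per_unit_phase_differences]
    if len(units) < 1:
        raise ValidationError("phase_lag_summary needs >= 1 unit")
    unit_means = np.array([np.angle(np.exp(1j * d).mean()) for d in units])
    group = np.exp(1j * unit_means).mean()
    return LagSummary(
        mean_lag=float(np.angle(group)),
        resultant_length=float(np.abs(group)),
        per_unit_lags=unit_means,
    )


@dataclass
class PsiResult:
    """Directed phase-slope connectivity for one channel pair and band.

    ``psi > 0`` means ``channel_a`` leads ``channel_b``; exactly antisymmetric
    under swapping the pair. ``z`` is the trial-shuffle surrogate z-score.
    """

    psi: float
    z: float
    p_perm: float
    null_mean: float
    null_sd: float
    band: tuple
    window: tuple
    n_perm: int
    seed: int
    channel_a: str
    channel_b: str
    freqs: np.ndarray = None
    coherency: np.ndarray = None


def _hann_spectra(x, fs):
    """Hanning-tapered rFFT per trial; returns (spectra, freqs)."""
    n = x.shape[-1]
    taper = np.hanning(n)
    spec = np.fft.rfft(x * taper, axis=-1)
    return spec, np.fft.rfftfreq(n, 1.0 / fs)


def psi_from_spectra(spec_a, spec_b, freqs, band) -> float:
    """PSI from per-trial spectra (trials on first axis) over ``band`` Hz.

    The complex arithmetic is carried in explicit real/imaginary components:
    element products commute and subtractions negate exactly in IEEE floats,
    so ``psi(a, b) == -psi(b, a)`` holds to the bit and identical channels
    give exactly zero (the coherency is then a real quantity).
    """
    ra, ia = spec_a.real, spec_a.imag
    rb, ib = spec_b.real, spec_b.imag
    # S_ab = <A conj(B)>: re = <ra rb + ia ib>, im = <ia rb - ra ib>
    s_re = (ra * rb + ia * ib).mean(axis=0)
    s_im = (ia * rb - ra * ib).mean(axis=0)
    s_aa = (ra * ra + ia * ia).mean(axis=0)
    s_bb = (rb * rb + ib * ib).mean(axis=0)
    denom = np.sqrt(s_aa * s_bb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = denom > 0
        c_re = np.where(ok, s_re / denom, np.nan)
        c_im = np.where(ok, s_im / denom, np.nan)
    in_band = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    idx = np.flatnonzero(in_band)
    if idx.size < 2:
        raise ValidationError(
            f"band {band} spans fewer than 2 frequency bins "
            f"(resolution {freqs[1] - freqs[0]:.3g} Hz)"
        )
    lo, hi = idx[:-1], idx[1:]
    # Im( conj(C(f)) C(f+df) ) = re_f * im_{f+df} - im_f * re_{f+df}
    pairs = c_re[lo] * c_im[hi] - c_im[lo] * c_re[hi]
    return float(np.nansum(pairs))


def psi(
    rec: EpochedRecording,
    pair=(0, 1),
    band: tuple = (5.0, 11.0),
    window: tuple = (-0.8, 0.0),
    n_perm: int = 200,
    seed: int = 0,
    trials=None,
) -> PsiResult:
    """Phase slope index of a channel pair with trial-shuffle inference.

    A single Hanning taper spans the whole analysis window per trial (1.25 Hz
    resolution for the default 800 ms window), with trials as the spectral
    observations. ``trials`` optionally restricts to a trial subset (used by
    the hit/miss contrast).
    """
    ia = pair[0] if isinstance(pair[0], (int, np.integer)) else rec.channel_index(pair[0])
    ib = pair[1] if isinstance(pair[1], (int, np.integer)) else rec.channel_index(pair[1])
    if ia == ib:
        raise ValidationError("PSI needs two distinct channels")
    if window[0] < rec.time[0] - 1e-9 or window[1] > rec.time[-1] + 1e-9:
        raise ValidationError("PSI window extends outside the epoch")
    if band[1] >= rec.fs / 2:
        raise ValidationError("PSI band exceeds Nyquist")
    sel = (rec.time >= window[0] - 1e-12) & (rec.time <= window[1] + 1e-12)
    data = rec.data if trials is None else rec.data[np.asarray(trials)]
    xa = data[:, ia, :][:, sel]
    xb = data[:, ib, :][:, sel]
    sa, freqs = _hann_spectra(xa, rec.fs)
    sb, _ = _hann_spectra(xb, rec.fs)
    observed = psi_from_spectra(sa, sb, freqs, band)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(sa.shape[0])
        null[p] = psi_from_spectra(sa[perm], sb, freqs, band)
    zmap = _z_from_null(np.atleast_1d(observed), null[:, None], n_perm, seed)
    labels = rec.channel_labels
    return PsiResult(
        psi=observed,
        z=float(zmap.z[0]),
        p_perm=float(zmap.p_perm[0]),
        null_mean=float(zmap.null_mean[0]),
        null_sd=float(zmap.null_sd[0]),
        band=tuple(band),
        window=tuple(window),
        n_perm=n_perm,
        seed=seed,
        channel_a=labels[ia],
        channel_b=labels[ib],
        freqs=freqs,
    )


@dataclass
class ConditionContrast:
    """Hit/miss contrast of a metric under trial-count-balanced subsampling."""

    value_hits: float
    value_misses: float
    difference: float
    n_per_condition: int
    n_draws: int
    z: float = None
    p_perm: float = None


def condition_contrast(
    metric_fn,
    rec: EpochedRecording,
    n_subsample_draws: int = 25,
    seed: int = 0,
    n_label_perm: int = 0,
) -> ConditionContrast:
    """Contrast ``metric_fn`` between hits and misses at balanced trial counts.

    The larger condition is repeatedly subsampled (without replacement) to the
    smaller condition's count and the metric averaged over draws; the smaller
    condition is evaluated once on all its trials. ``metric_fn`` maps an
    :class:`EpochedRecording` (single condition) to a scalar. With
    ``n_label_perm > 0`` an outcome-label permutation null for the difference
    is added (z and one-sided p for difference > 0).
    """
    rec.require_both_outcomes(min_per_class=5)
    rng = np.random.default_rng(seed)

    def balanced_difference(outcome, rng_draw):
        hits = np.flatnonzero(outcome == 1)
        misses = np.flatnonzero(outcome == 0)
        small, large = (hits, misses) if hits.size <= misses.size else (misses, hits)
        v_small = metric_fn(rec.select_trials(small))
        draws = [
            metric_fn(rec.select_trials(rng_draw.choice(large, small.size, replace=False)))
            for _ in range(n_subsample_draws)
        ]
        v_large = float(np.mean(draws))
        if hits.size <= misses.size:
            return v_small, v_large, small.size
        return v_large, v_small, small.size

    v_h, v_m, n_small = balanced_difference(rec.outcome, rng)
    diff = v_h - v_m
    z = p = None
    if n_label_perm > 0:
        null = np.empty(n_label_perm)
        for i in range(n_label_perm):
            null[i] = np.subtract(
                *balanced_difference(rng.permutation(rec.outcome), rng)[:2]
            )
        sd = null.std(ddof=1)
        z = float((diff - null.mean()) / sd) if sd > 0 else np.nan
        p = float((1.0 + (null >= diff).sum()) / (1.0 + n_label_perm))
    return ConditionContrast(
        value_hits=float(v_h),
        value_misses=float(v_m),
        difference=float(diff),
        n_per_condition=n_small,
        n_draws=n_subsample_draws,
        z=z,
        p_perm=p,
    )
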