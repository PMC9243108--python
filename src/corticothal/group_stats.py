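"""Group-level inference: cluster-based sign-flip permutation tests and
JZS Bayes factors.

The cluster test controls multiple comparisons over a time-frequency region
of interest (default: pre-stimulus, -800..0 ms, 6-14 Hz). Per cell, a
one-sample t across units is thresholded (two-sided at ``cluster_alpha`` on
the t distribution); 4-connected suprathreshold cells form clusters scored by
mass (summed t), and the observed masses are compared with the null
distribution of the maximum cluster mass under random sign flips of whole
unit maps — fully enumerated (2^n flips, identity included) for n <= 12
units, sampled otherwise. Cluster p-values are therefore bounded below by
1/2^n.

The Bayes factor is the one-sample JZS BF10: a Cauchy(0, r) prior on the
standardized effect, integrated numerically (Zellner-Siow mixture-of-g form).
Default prior scale r = sqrt(2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, ndimage, stats

from .exceptions import NumericalError, ValidationError


@dataclass
class ClusterResult:
    """Suprathreshold clusters with mass statistics and permutation p-values."""

    clusters: list  # each: {"cells": (freq_idx, time_idx), "mass": float, "p_clus": float}
    t_map: np.ndarray
    mask: np.ndarray
    n_perm: int
    roi: dict
    tail: str
    cluster_alpha: float

    @property
    def min_p(self) -> float:
        return min((c["p_clus"] for c in self.clusters), default=1.0)


def _all_sign_flips(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.uint64)
    bits = np.arange(n, dtype=np.uint64)
    return 1.0 - 2.0 * ((codes[:, None] >> bits[None, :]) & np.uint64(1)).astype(float)


def _t_from_signed(maps_flat, signs, sumsq):
    """Vectorized one-sample t maps under sign flips.

    Sign flips leave per-cell sums of squares unchanged, so only the mean
    moves: sd^2 = (sumsq - n*mean^2) / (n-1).
    """
    n = maps_flat.shape[0]
    mean = signs @ maps_flat / n
    var = (sumsq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, mean / np.sqrt(var / n), np.sign(mean) * np.inf)


def _clusters_and_masses(t_map, t_crit, mask, sign):
    """Label 4-connected suprathreshold cells; returns (labels, masses)."""
    supra = mask & np.isfinite(t_map) & (sign * t_map > t_crit)
    labels, n_lab = ndimage.label(supra)  # default structure = edge adjacency
    if n_lab == 0:
        return labels, np.array([])
    masses = ndimage.sum_labels(t_map, labels, index=np.arange(1, n_lab + 1))
    return labels, masses


def cluster_permutation_test(
    maps,
    freqs,
    times,
    roi_freq: tuple = (6.0, 14.0),
    roi_time: tuple = (-0.8, 0.0),
    cluster_alpha: float = 0.05,
    tail: str = "positive",
    n_perm: int = None,
    seed: int = 0,
    valid_mask=None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test over per-unit (freq, time) maps.

    ``maps`` is (n_units, n_freqs, n_times); ``n_perm=None`` enumerates all
    2^n flips when n_units <= 12 and samples 1000 otherwise. ``valid_mask``
    optionally excludes cells (e.g. wavelet-edge-contaminated ones) on top of
    the ROI restriction.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValidationError("maps must be (n_units, n_freqs, n_times)")
    n_units = maps.shape[0]
    if n_units < 3:
        raise ValidationError("cluster test needs >= 3 units")
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    if maps.shape[1:] != (freqs.size, times.size):
        raise ValidationError("maps shape does not match the freq/time grids")
    if tail not in ("positive", "negative", "two-sided"):
        raise ValidationError(f"unknown tail {tail!r}")
    mask = (
        (freqs[:, None] >= roi_freq[0] - 1e-9)
        & (freqs[:, None] <= roi_freq[1] + 1e-9)
        & (times[None, :] >= roi_time[0] - 1e-9)
        & (times[None, :] <= roi_time[1] + 1e-9)
    )
    if valid_mask is not None:
        mask = mask & np.asarray(valid_mask, dtype=bool)
    mask = mask & np.all(np.isfinite(maps), axis=0)
    if not mask.any():
        raise ValidationError("ROI is empty after masking")
    if np.any(np.all(np.isnan(maps.reshape(n_units, -1)), axis=1)):
        raise ValidationError("a unit's map is entirely NaN")

    shape = maps.shape[1:]
    maps_flat = np.where(mask, maps, 0.0).reshape(n_units, -1)
    sumsq = (maps_flat**2).sum(axis=0)
    t_crit = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n_units - 1))
    t_obs = _t_from_signed(maps_flat, np.ones((1, n_units)), sumsq)[0].reshape(shape)

    tails = {"positive": [1.0], "negative": [-1.0], "two-sided": [1.0, -1.0]}[tail]
    observed = []
    for sgn in tails:
        labels, masses = _clusters_and_masses(t_obs, t_crit, mask, sgn)
        for lab, mass in enumerate(masses, start=1):
            cells = np.nonzero(labels == lab)
            observed.append({"cells": cells, "mass": float(mass)})

    if n_perm is None and n_units <= 12:
        signs = _all_sign_flips(n_units)
    else:
        rng = np.random.default_rng(seed)
        k = 1000 if n_perm is None else int(n_perm)
        if k < 2:
            raise ValidationError("n_perm must be >= 2")
        signs = rng.choice([-1.0, 1.0], size=(k, n_units))
    n_total = signs.shape[0]
    t_null = _t_from_signed(maps_flat, signs, sumsq)
    null_max = np.zeros(n_total)
    for i in range(n_total):
        tm = t_null[i].reshape(shape)
        best = 0.0
        for sgn in tails:
            _, masses = _clusters_and_masses(tm, t_crit, mask, sgn)
            if masses.size:
                best = max(best, float(np.abs(masses).max()))
        null_max[i] = best
    for c in observed:
        c["p_clus"] = float((null_max >= abs(c["mass"]) - 1e-12).mean())
    observed.sort(key=lambda c: abs(c["mass"]), reverse=True)
    return ClusterResult(
        clusters=observed, t_map=t_obs, mask=mask, n_perm=int(n_total),
        roi={"freq": tuple(roi_freq), "time": tuple(roi_time)},
        tail=tail, cluster_alpha=cluster_alpha,
    )


@dataclass
class BayesResult:
    """One-sample JZS Bayes factor (evidence for H1 over H0)."""

    t: float
    n: int
    r: float
    bf10: float


def jzs_bayes_factor(t: float, n: int, r: float = np.sqrt(2) / 2) -> BayesResult:
    """One-sample JZS BF10 with a Cauchy(0, r) prior on the effect size.

    Computed by quadrature over the Zellner-Siow mixture: g carries an
    inverse-gamma(1/2, 1/2) prior, scaled by n r^2.
    """
    if n < 2:
        raise ValidationError("jzs_bayes_factor needs n >= 2")
    if r <= 0:
        raise ValidationError("prior scale r must be > 0")
    nu = n - 1
    t2 = float(t) ** 2

    def integrand(g):
        w = 1.0 + n * g * r**2
        return (
            w ** (-0.5)
            * (1.0 + t2 / (w * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** (-0.5)
            * g ** (-1.5)
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > max(1e-8, 1e-6 * num):
        raise NumericalError(
            f"JZS quadrature did not converge (value={num}, err={err})"
        )
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    return BayesResult(t=float(t), n=int(n), r=float(r), bf10=float(num / den))


def interpret_bf(bf10: float) -> str:
    """Heuristic evidence label: <3 anecdotal, 3-10 moderate, >10 strong."""
    if bf10 <= 0:
        raise ValidationError("bf10 must be positive")
    if bf10 < 3.0:
        return "anecdotal"
    if bf10 <= 10.0:
        return "moderate"
    return "strong"
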