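"""Epoched recording container.

The universal input of the package: a trials x channels x samples array with
a uniform time axis (0 s = stimulus onset) and a per-trial binary behavioral
outcome (1 = hit, 0 = miss).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError


@dataclass
class EpochedRecording:
    """Epoched multi-channel time series with per-trial outcomes.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in arbitrary units. Must be finite.
    time : ndarray, shape (n_samples,)
        Seconds relative to stimulus onset; strictly increasing, uniform
        at 1/fs.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel (e.g. ``["mPFC", "MD"]``).
    outcome : ndarray, shape (n_trials,)
        Binary per-trial outcome; 1 = hit, 0 = miss.
    """

    data: np.ndarray
    time: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=list)
    outcome: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be (trials, channels, samples); got ndim={self.data.ndim}"
            )
        n_trials, n_channels, n_samples = self.data.shape
        if self.time.shape != (n_samples,):
            raise ValidationError(
                f"time has {self.time.size} samples but data has {n_samples}"
            )
        dt = np.diff(self.time)
        if n_samples > 1 and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValidationError("time axis must be uniform at 1/fs and increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains NaN or Inf")
        if self.outcome is None:
            raise ValidationError("outcome vector is required")
        self.outcome = np.asarray(self.outcome)
        if self.outcome.shape != (n_trials,):
            raise ValidationError(
                f"outcome has length {self.outcome.size}, expected {n_trials}"
            )
        if not np.isin(self.outcome, [0, 1]).all():
            raise ValidationError("outcome must be binary (0 = miss, 1 = hit)")
        self.outcome = self.outcome.astype(np.uint8)
        if len(self.channel_labels) != n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for {n_channels} channels"
            )
        self.channel_labels = [str(c) for c in self.channel_labels]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"channel {label!r} not found; have {self.channel_labels}"
            ) from None

    def select_trials(self, idx) -> "EpochedRecording":
        """Return a copy restricted to the given trial indices/boolean mask."""
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], outcome=self.outcome[idx])

    def require_both_outcomes(self, min_per_class: int = 2) -> None:
        """Raise unless both hit and miss classes have enough trials."""
        n_hit = int(self.outcome.sum())
        n_miss = int(self.n_trials - n_hit)
        if n_hit < min_per_class or n_miss < min_per_class:
            raise ValidationError(
                f"need >= {min_per_class} trials per outcome class; "
                f"got {n_hit} hits / {n_miss} misses"
            )
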