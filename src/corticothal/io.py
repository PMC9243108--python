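"""HDF5/CSV persistence for recordings, spectral estimates, and statistic maps.

Epochs container layout (format_version "1"):

* ``/data``   — float64, (n_trials, n_channels, n_samples)
* ``/time``   — float64 seconds, (n_samples,)
* ``/outcome``— uint8, (n_trials,)
* root attrs  — ``fs`` (Hz), ``channel_labels``, ``format_version``

Spectral estimates store the complex coefficients as paired real arrays plus
the frequency/time grids. Statistic maps export to long-format CSV
(freq, time, observed, z, p_perm).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .data import EpochedRecording
from .exceptions import ValidationError
from .phase_stats import SurrogateZMap
from .spectral import SpectralEstimate
from .synthetic import StaircaseTrace

FORMAT_VERSION = "1"


def write_epochs(rec: EpochedRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype("<f8"))
        f.create_dataset("time", data=rec.time.astype("<f8"))
        f.create_dataset("outcome", data=rec.outcome.astype(np.uint8))
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        f.attrs["format_version"] = FORMAT_VERSION


def read_epochs(path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValidationError(
                f"unknown epochs format_version {version!r} (expected {FORMAT_VERSION!r})"
            )
        for name in ("data", "time", "outcome"):
            if name not in f:
                raise ValidationError(f"epochs file is missing dataset '/{name}'")
        data = f["data"][()]
        time = f["time"][()]
        outcome = f["outcome"][()]
        fs = float(f.attrs["fs"])
        labels = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["channel_labels"]
        ]
    return EpochedRecording(
        data=data, time=time, fs=fs, channel_labels=labels, outcome=outcome
    )


def write_spectral(spec: SpectralEstimate, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coeff_real", data=spec.coeff.real)
        f.create_dataset("coeff_imag", data=spec.coeff.imag)
        f.create_dataset("freqs", data=spec.freqs)
        f.create_dataset("times", data=spec.times)
        if spec.outcome is not None:
            f.create_dataset("outcome", data=spec.outcome.astype(np.uint8))
        f.attrs["n_cycles"] = spec.n_cycles
        f.attrs["source_fs"] = spec.source_fs
        f.attrs["n_source_samples"] = spec.n_source_samples
        f.attrs["channel_labels"] = [str(c) for c in spec.channel_labels]
        f.attrs["format_version"] = FORMAT_VERSION


def read_spectral(path) -> SpectralEstimate:
    with h5py.File(path, "r") as f:
        for name in ("coeff_real", "coeff_imag", "freqs", "times"):
            if name not in f:
                raise ValidationError(f"spectral file is missing dataset '/{name}'")
        coeff = f["coeff_real"][()] + 1j * f["coeff_imag"][()]
        outcome = f["outcome"][()] if "outcome" in f else None
        return SpectralEstimate(
            coeff=coeff,
            freqs=f["freqs"][()],
            times=f["times"][()],
            n_cycles=float(f.attrs["n_cycles"]),
            source_fs=float(f.attrs["source_fs"]),
            n_source_samples=int(f.attrs["n_source_samples"]),
            channel_labels=[
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs["channel_labels"]
            ],
            outcome=outcome,
        )


def zmap_to_frame(zmap: SurrogateZMap, freqs, times) -> pd.DataFrame:
    """Long-format (freq, time, observed, z, p_perm) table of a surrogate z map."""
    fgrid, tgrid = np.meshgrid(freqs, times, indexing="ij")
    return pd.DataFrame(
        {
            "freq": fgrid.ravel(),
            "time": tgrid.ravel(),
            "observed": zmap.observed.ravel(),
            "z": zmap.z.ravel(),
            "p_perm": zmap.p_perm.ravel(),
        }
    )


def staircase_to_csv(trace: StaircaseTrace, path) -> None:
    pd.DataFrame(
        {
            "trial": np.arange(1, trace.n_trials + 1),
            "level": trace.level,
            "correct": trace.correct.astype(int),
        }
    ).to_csv(path, index=False)


def staircase_from_csv(path) -> StaircaseTrace:
    df = pd.read_csv(path)
    for col in ("trial", "level", "correct"):
        if col not in df.columns:
            raise ValidationError(f"staircase CSV is missing column {col!r}")
    correct = df["correct"].to_numpy().astype(bool)
    n = len(df)
    return StaircaseTrace(
        level=df["level"].to_numpy(dtype=float),
        correct=correct,
        asymptote_estimate=float(correct[n // 2 :].mean()),
    )
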