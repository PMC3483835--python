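"""Noisy readout of simulated trajectories (immunoblot / count densitometry).

Quantitative blotting and scintillation counting report a positive signal
proportional to abundance with roughly constant *relative* error, so the
noise model is multiplicative lognormal with mean exactly 1 (the sigma of
the underlying normal is set from the requested coefficient of variation
and the -sigma^2/2 mean correction is applied).  Signals are then
normalized to the mean of the first-time-point replicates, mirroring the
percent-of-initial convention of chase experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import ParameterError
from .scenarios import TimeCourse

__all__ = ["NoiseModel", "MeasurementSet", "sample_measurements", "read_measurements"]

CHANNELS = ("total", "labeled", "heavy_fraction")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    cv
        Coefficient of variation of a single observation (0.10 is a
        typical careful densitometry value).  cv = 0 gives the noiseless
        trajectory back.
    replicates
        Independent measurements per time point.
    seed
        Seed for the generator; identical seeds give identical output.
    detection_floor
        Relative signal below which observations are censored (clipped);
        0 disables censoring.
    """

    cv: float = 0.10
    replicates: int = 3
    seed: int = 0
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cv) and self.cv >= 0):
            raise ParameterError(f"cv must be >= 0 and finite, got {self.cv!r}")
        if int(self.replicates) < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates!r}")
        if not (math.isfinite(self.detection_floor) and self.detection_floor >= 0):
            raise ParameterError(f"detection_floor must be >= 0, got {self.detection_floor!r}")


@dataclass(frozen=True)
class MeasurementSet:
    """Replicate signals per time, normalized to the t0 replicate mean."""

    times: np.ndarray  # (n_times,)
    signals: np.ndarray  # (n_times, n_replicates)
    normalization: str = "t0-mean"

    @property
    def replicate_means(self) -> np.ndarray:
        return self.signals.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n_t, n_r = self.signals.shape
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, n_r),
                "replicate": np.tile(np.arange(1, n_r + 1), n_t),
                "signal": self.signals.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def normalize_t0_mean(times: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Scale all signals by the mean signal at the earliest time (idempotent)."""
    ref = signals[np.argmin(times)].mean()
    if ref <= 0:
        raise ParameterError("cannot normalize: mean t0 signal is not positive")
    return signals / ref


def sample_measurements(tc: TimeCourse, channel: str, nm: NoiseModel) -> MeasurementSet:
    """Draw noisy replicate measurements of one channel of a time course.

    Each observation is the true value times an independent lognormal
    factor of mean 1 and coefficient of variation ``nm.cv``, clipped at
    the detection floor, then normalized to the t = 0 replicate mean.
    """
    if channel not in CHANNELS:
        raise ParameterError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if np.size(tc.times) == 0:
        raise ParameterError("empty time course")
    if channel == "total":
        truth = np.asarray(tc.protein_total, dtype=float)
    elif channel == "labeled":
        if not tc.labeled_present:
            raise ParameterError("channel 'labeled' absent: time course has no labeled pool")
        truth = np.asarray(tc.protein_labeled, dtype=float)
    else:  # heavy_fraction
        if not tc.labeled_present:
            raise ParameterError("channel 'heavy_fraction' absent: time course has no labeled pool")
        total = np.asarray(tc.protein_total, dtype=float)
        if np.any(total <= 0):
            raise ParameterError("heavy_fraction undefined where total protein is zero")
        truth = np.asarray(tc.protein_labeled, dtype=float) / total

    times = np.asarray(tc.times, dtype=float)
    if channel != "heavy_fraction":
        # work on the relative-signal scale so the detection floor is
        # commensurate with the t0-normalized output
        ref = truth[np.argmin(times)]
        if ref <= 0:
            raise ParameterError("cannot normalize: true signal at t0 is not positive")
        truth = truth / ref

    rng = np.random.default_rng(nm.seed)
    n_t = truth.size
    n_r = int(nm.replicates)
    if nm.cv > 0:
        sigma = math.sqrt(math.log1p(nm.cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(n_t, n_r))
    else:
        factors = np.ones((n_t, n_r))
    signals = truth[:, None] * factors
    if nm.detection_floor > 0:
        signals = np.maximum(signals, nm.detection_floor)
    if channel == "heavy_fraction":
        # already a ratio in [0, 1] that starts at zero: t0 normalization
        # is undefined and unnecessary
        return MeasurementSet(times=times, signals=signals, normalization="none")
    signals = normalize_t0_mean(times, signals)
    return MeasurementSet(times=times, signals=signals)


def read_measurements(path) -> MeasurementSet:
    """Read a (time_h, replicate, signal) table back into a MeasurementSet.

    Requires the same replicate count at every time; rows may appear in
    any order.  Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_h", "replicate", "signal") if c not in df.columns]
    if missing:
        raise ParameterError(f"measurement table missing columns: {missing}")
    bad = df.index[df[["time_h", "replicate", "signal"]].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +2: header + 1-based
        raise ParameterError(f"malformed rows at lines {lines}")
    counts = df.groupby("time_h")["signal"].size()
    if counts.nunique() != 1:
        raise ParameterError("unequal replicate counts across time points")
    times = np.array(sorted(counts.index), dtype=float)
    n_r = int(counts.iloc[0])
    signals = np.empty((times.size, n_r))
    for i, t in enumerate(times):
        sub = df[df["time_h"] == t].sort_values("replicate")
        signals[i] = sub["signal"].to_numpy(dtype=float)
    return MeasurementSet(times=times, signals=signals)
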