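"""Filtering, epoching, averaging and windowing of SEP recordings.

The somatosensory evoked potential (SEP) pipeline operates on trial-wise
epochs sampled at 2 kHz: a 3-299 Hz zero-phase band-pass with 60 Hz
power-line notches, per-epoch baseline correction over the 100 ms
pre-stimulus interval, exclusion of the first 3 ms after stimulus onset
(stimulation artifact), trial averaging, and extraction of the scalp
topography averaged over the P20/N20 analysis window (20 +/- 3 ms).
All parameters are identical across stimulation conditions by construction:
the same function defaults apply to every condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "SepWaveform",
    "filter_signals",
    "epoch_and_average",
    "extract_window",
    "window_sample_indices",
]

DEFAULT_BAND_HZ = (3.0, 299.0)
DEFAULT_NOTCH_HZ = (60.0, 120.0, 180.0, 240.0)
DEFAULT_ARTIFACT_MS = 3.0


@dataclass
class EpochSet:
    """Trial-wise scalp recordings: ``data`` is (trials, channels, samples) in uV.

    ``t0_ms`` is the stimulus latency measured from the first sample, so the
    sample at index ``round(t0_ms * fs / 1000)`` is stimulus onset (t = 0).
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    channels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be (trials, channels, samples)")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        span = self.data.shape[2] * 1000.0 / self.fs_hz
        if not (0.0 <= self.t0_ms < span):
            raise ValueError(f"t0_ms={self.t0_ms} outside epoch span [0, {span}) ms")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel label count does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times relative to stimulus onset (ms)."""
        n = self.data.shape[2]
        return np.arange(n) * 1000.0 / self.fs_hz - self.t0_ms

    def save(self, path: str) -> None:
        """Write the array as .npy with a JSON sidecar next to it."""
        np.save(path if path.endswith(".npy") else path + ".npy", self.data)
        side = (path[:-4] if path.endswith(".npy") else path) + ".json"
        with open(side, "w") as fh:
            json.dump(
                {
                    "fs_hz": self.fs_hz,
                    "t0_ms": self.t0_ms,
                    "channels": list(self.channels),
                    "meta": self.meta,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str) -> "EpochSet":
        base = path[:-4] if path.endswith(".npy") else path
        data = np.load(base + ".npy")
        with open(base + ".json") as fh:
            side = json.load(fh)
        return cls(data, side["fs_hz"], side["t0_ms"], side["channels"], side.get("meta", {}))


@dataclass
class SepWaveform:
    """Trial-averaged SEP: ``data`` is (channels, samples) in uV.

    ``excluded`` flags samples inside the stimulation-artifact interval; they
    are carried (not interpolated) and dropped from any later window average.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    channels: list[str]
    n_trials: int
    excluded: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SepWaveform data must be (channels, samples)")
        if self.excluded is None:
            self.excluded = np.zeros(self.data.shape[1], dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return np.arange(n) * 1000.0 / self.fs_hz - self.t0_ms


def _apply_along_last(data: np.ndarray, fun) -> np.ndarray:
    flat = data.reshape(-1, data.shape[-1])
    out = fun(flat)
    return out.reshape(data.shape)


def filter_signals(
    epochs: "EpochSet | np.ndarray",
    fs_hz: float | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    notch_hz_list: tuple[float, ...] = DEFAULT_NOTCH_HZ,
    band_order: int = 4,
    notch_q: float = 35.0,
):
    """Zero-phase band-pass followed by notch filters.

    Defaults: 3-299 Hz Butterworth band-pass (4th order, forward-backward)
    and notches at 60 Hz and its harmonics 120/180/240 Hz.  Accepts either an
    :class:`EpochSet` (returns a filtered copy) or a bare array whose last
    axis is time (``fs_hz`` then required).
    """
    if isinstance(epochs, EpochSet):
        filt = filter_signals(epochs.data, epochs.fs_hz, band_hz, notch_hz_list, band_order, notch_q)
        meta = dict(epochs.meta)
        meta["filter"] = {
            "band_hz": list(band_hz),
            "notch_hz": list(notch_hz_list),
            "band_order": band_order,
            "zero_phase": True,
        }
        return replace(epochs, data=filt, meta=meta)

    if fs_hz is None:
        raise ValueError("fs_hz required when filtering a bare array")
    nyq = fs_hz / 2.0
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ValueError("band edges must satisfy 0 < low < high")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({nyq} Hz)")
    data = np.asarray(epochs, dtype=float)
    sos = signal.butter(band_order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    out = _apply_along_last(data, lambda x: signal.sosfiltfilt(sos, x, axis=-1))
    for f0 in notch_hz_list:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist")
        b, a = signal.iirnotch(f0, notch_q, fs=fs_hz)
        out = _apply_along_last(out, lambda x, b=b, a=a: signal.filtfilt(b, a, x, axis=-1))
    return out


def epoch_and_average(
    epochs: EpochSet,
    baseline_ms: tuple[float, float] | None = None,
    artifact_exclusion_ms: float = DEFAULT_ARTIFACT_MS,
) -> SepWaveform:
    """Baseline-correct each trial over the pre-stimulus interval and average.

    ``baseline_ms`` is relative to stimulus onset; the default is the full
    pre-stimulus segment ``[-t0, 0)``.  Samples with ``0 <= t <
    artifact_exclusion_ms`` are flagged as excluded in the result.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot average zero trials")
    t = epochs.times_ms
    if baseline_ms is None:
        baseline_ms = (-epochs.t0_ms, 0.0)
    bsel = (t >= baseline_ms[0] - 1e-9) & (t < baseline_ms[1] - 1e-9)
    if not bsel.any():
        raise ValueError("baseline interval contains no samples")
    data = epochs.data - epochs.data[:, :, bsel].mean(axis=2, keepdims=True)
    avg = data.mean(axis=0)
    excluded = (t >= -1e-9) & (t < artifact_exclusion_ms - 1e-9)
    return SepWaveform(
        data=avg,
        fs_hz=epochs.fs_hz,
        t0_ms=epochs.t0_ms,
        channels=list(epochs.channels),
        n_trials=epochs.n_trials,
        excluded=excluded,
        meta={"baseline_ms": list(baseline_ms), "artifact_exclusion_ms": artifact_exclusion_ms},
    )


def window_sample_indices(
    wave: SepWaveform, center_ms: float = 20.0, halfwidth_ms: float = 3.0
) -> np.ndarray:
    """Indices of non-excluded samples with |t - center| <= halfwidth."""
    t = wave.times_ms
    sel = np.abs(t - center_ms) <= halfwidth_ms + 1e-9
    return np.flatnonzero(sel & ~wave.excluded)


def extract_window(
    wave: SepWaveform,
    center_ms: float = 20.0,
    halfwidth_ms: float = 3.0,
    mode: str = "mean",
    rereference: bool = True,
) -> np.ndarray:
    """Scalp topography of the analysis window, one value per channel.

    ``mode='mean'`` (default) averages over the window samples; ``'peak'``
    picks the sample of maximal global field power within the window.  The
    result is re-referenced to the common average so it sums to zero across
    channels, matching a lead field built with any single reference.
    """
    t = wave.times_ms
    if center_ms - halfwidth_ms < t[0] - 1e-9 or center_ms + halfwidth_ms > t[-1] + 1e-9:
        raise ValueError("analysis window extends outside the epoch")
    idx = window_sample_indices(wave, center_ms, halfwidth_ms)
    if idx.size == 0:
        raise ValueError("analysis window contains no usable samples")
    if mode == "mean":
        vec = wave.data[:, idx].mean(axis=1)
    elif mode == "peak":
        gfp = (wave.data[:, idx] ** 2).sum(axis=0)
        vec = wave.data[:, idx[np.argmax(gfp)]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if rereference:
        vec = vec - vec.mean()
    return vec
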