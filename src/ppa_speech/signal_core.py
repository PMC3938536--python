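"""Waveform representation, WAV I/O, and intensity-contour computation.

All acoustic measures in this package consume the two primitives defined
here: a mono :class:`Waveform` with samples in ``[-1, 1]`` and an
:class:`IntensityContour` of windowed dB values.

Conventions
-----------
* Time is in seconds; intervals are half-open ``[start, end)``.
* Intensity is dB relative to full scale (a full-scale constant signal is
  0 dB).  Recordings are uncalibrated, so only relative levels matter;
  downstream silence thresholds are range-relative and the dB reference
  cancels.
* Contour frames are indexed by their centre time; the contour covers
  ``[window_s/2, duration - window_s/2]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal.windows import hann

from .errors import ComputationError, ValidationError

__all__ = [
    "Interval",
    "Waveform",
    "IntensityContour",
    "read_wav",
    "write_wav",
    "intensity_contour",
    "peak_db",
    "DEFAULT_WINDOW_S",
    "DEFAULT_HOP_S",
    "DEFAULT_FLOOR_DB",
]

DEFAULT_WINDOW_S = 0.032
DEFAULT_HOP_S = 0.008
DEFAULT_FLOOR_DB = -96.0


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return Interval(lo, hi) if lo < hi else None

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio with dimensionless samples in ``[-1, 1]``."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValidationError(f"waveform samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("waveform samples must all be finite")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be > 0 Hz, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def scaled(self, gain: float) -> "Waveform":
        """Return a copy with all samples multiplied by ``gain``."""
        return Waveform(self.samples * gain, self.rate)


@dataclass(frozen=True)
class IntensityContour:
    """Time-indexed intensity values in dB (relative scale).

    ``times`` are frame-centre times, strictly increasing and spaced by
    ``hop_s``; ``values`` holds one dB value per frame, floored at the
    configured dB floor.
    """

    times: np.ndarray
    values: np.ndarray
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.size != values.size or times.size == 0:
            raise ValidationError("contour times/values must be non-empty and equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("contour times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValidationError("contour values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def start(self) -> float:
        """Left edge of the analysed span (first frame's window start, ~0)."""
        return max(0.0, float(self.times[0]) - self.window_s / 2)

    @property
    def end(self) -> float:
        """Right edge of the analysed span (last frame's window end)."""
        return float(self.times[-1]) + self.window_s / 2

    def span(self) -> Interval:
        return Interval(self.start, self.end)

    def shifted(self, offset_db: float) -> "IntensityContour":
        return IntensityContour(self.times, self.values + offset_db, self.window_s, self.hop_s)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "db": self.values})


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a RIFF/WAVE PCM or float file as a mono waveform in ``[-1, 1]``.

    Multi-channel files are averaged to mono.  Integer encodings are
    rescaled by their full-scale value (e.g. int16 by 32768).

    Raises
    ------
    ValidationError
        If the file is missing, not a readable WAV file, or uses an
        unsupported sample encoding.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ValidationError(f"WAV file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValidationError(f"could not read {path} as RIFF/WAVE: {exc}") from exc
    if data.ndim == 2:
        data = data.mean(axis=1)
    elif data.ndim != 1:
        raise ValidationError(f"unsupported channel layout in {path}: shape {data.shape}")

    kind = data.dtype
    if kind == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif kind == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif kind == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif kind in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValidationError(f"unsupported sample encoding in {path}: dtype {kind}")
    return Waveform(samples, float(rate))


def write_wav(path: str | os.PathLike, w: Waveform, encoding: str = "pcm16") -> None:
    """Write a waveform as 16-bit PCM (default) or 32-bit float WAV."""
    if encoding == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0)
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif encoding == "float32":
        data = w.samples.astype(np.float32)
    else:
        raise ValidationError(f"unsupported encoding {encoding!r} (use 'pcm16' or 'float32')")
    wavfile.write(os.fspath(path), int(round(w.rate)), data)


def intensity_contour(
    w: Waveform,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    floor_db: float = DEFAULT_FLOOR_DB,
) -> IntensityContour:
    """Windowed intensity contour in dB relative to full scale.

    Each frame value is ``10*log10`` of the Hann-weighted mean squared
    sample over a ``window_s`` window, floored at ``floor_db``.  Frames
    advance by ``hop_s`` and are indexed by their centre times, so the
    contour covers ``[window_s/2, duration - window_s/2]``.

    Raises
    ------
    ValidationError
        If the waveform is shorter than one analysis window or the
        window/hop parameters are invalid.
    """
    if window_s <= 0 or hop_s <= 0:
        raise ValidationError(f"window_s and hop_s must be > 0, got {window_s}, {hop_s}")
    n_win = int(round(window_s * w.rate))
    n_hop = int(round(hop_s * w.rate))
    if n_win < 2 or n_hop < 1:
        raise ValidationError("window/hop too short for the sampling rate")
    if w.samples.size < n_win:
        raise ValidationError(
            f"waveform ({w.duration:.4f} s) is shorter than one analysis window "
            f"({window_s:.4f} s)"
        )
    taper = hann(n_win, sym=False)
    taper /= taper.sum()
    frames = np.lib.stride_tricks.sliding_window_view(w.samples, n_win)[::n_hop]
    mean_sq = (frames * frames) @ taper
    floor_power = 10.0 ** (floor_db / 10.0)
    values = 10.0 * np.log10(np.maximum(mean_sq, floor_power))
    times = (np.arange(values.size) * n_hop + n_win / 2.0) / w.rate
    return IntensityContour(times, values, window_s, hop_s)


def peak_db(c: IntensityContour, iv: Interval) -> float:
    """Maximum contour value among frames whose centre falls in ``iv``.

    Raises
    ------
    ValidationError
        If no frame centre falls inside the interval.
    """
    mask = (c.times >= iv.start) & (c.times < iv.end)
    if not mask.any():
        raise ValidationError(
            f"no contour frame centre falls in [{iv.start}, {iv.end}); "
            f"contour spans [{c.times[0]:.4f}, {c.times[-1]:.4f}]"
        )
    return float(c.values[mask].max())
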