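"""Silence detection in connected-speech recordings and summary metrics.

Silences are intensity-contour runs below a range-relative threshold,
post-processed with three rules (minimum silence duration, minimum
intervening speech duration, edge trimming) and summarised as proportion
of silence time (PST), median silence duration, and median absolute
deviation (MAD) of silence duration.

Rule application order (fixed, documented):

1. threshold the contour into sub-threshold runs,
2. absorb intervening speech runs shorter than ``min_speech_s`` into the
   surrounding silence,
3. discard silences shorter than ``min_silence_s``,
4. trim silences touching the start or end of the sample,
5. remove portions covered by caller-supplied exclusion intervals
   (non-speech bursts such as coughs); excluded time also leaves the PST
   denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .signal_core import (
    DEFAULT_FLOOR_DB,
    DEFAULT_HOP_S,
    DEFAULT_WINDOW_S,
    IntensityContour,
    Interval,
    Waveform,
    intensity_contour,
)

__all__ = [
    "SilenceConfig",
    "SilenceMetrics",
    "silence_threshold",
    "detect_silences",
    "silence_metrics",
    "analyze_waveform",
    "read_exclusions_csv",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SilenceConfig:
    """Parameters of the three silence criteria.

    ``threshold_frac`` positions the silence threshold at that fraction of
    the distance between the contour minimum and the reference intensity;
    the reference sits at ``ref_frac`` of the min-to-max range above the
    minimum (robust to irregular intensity bursts).
    """

    threshold_frac: float = 0.65
    ref_frac: float = 0.95
    min_silence_s: float = 0.015
    min_speech_s: float = 0.030

    def __post_init__(self) -> None:
        if not (0 < self.threshold_frac <= 1):
            raise ValidationError(f"threshold_frac must be in (0, 1], got {self.threshold_frac}")
        if not (0 < self.ref_frac <= 1):
            raise ValidationError(f"ref_frac must be in (0, 1], got {self.ref_frac}")
        if self.min_silence_s <= 0 or self.min_speech_s <= 0:
            raise ValidationError("minimum durations must be > 0")


@dataclass(frozen=True)
class SilenceMetrics:
    """Summary of detected silences over an analysed span.

    ``median_s`` and ``mad_s`` are ``None`` (undefined, not zero) when no
    silences were detected.
    """

    pst: float
    arcsin_pst: float
    median_s: float | None
    mad_s: float | None
    n_silences: int
    analysed_span: Interval

    def to_dict(self) -> dict:
        return {
            "pst": self.pst,
            "arcsin_pst": self.arcsin_pst,
            "median_ms": None if self.median_s is None else self.median_s * 1000.0,
            "mad_ms": None if self.mad_s is None else self.mad_s * 1000.0,
            "median_s": self.median_s,
            "mad_s": self.mad_s,
            "n_silences": self.n_silences,
            "span_start_s": self.analysed_span.start,
            "span_end_s": self.analysed_span.end,
        }


def silence_threshold(c: IntensityContour, cfg: SilenceConfig = SilenceConfig()) -> float:
    """Range-relative silence threshold in dB.

    ``T = I_min + threshold_frac * (I_ref - I_min)`` with
    ``I_ref = I_min + ref_frac * (I_max - I_min)``.  Adding a constant dB
    offset to the contour shifts ``T`` by exactly that offset.

    Raises
    ------
    ComputationError
        If the contour is flat (``I_max == I_min``).
    """
    i_min = float(c.values.min())
    i_max = float(c.values.max())
    if i_max - i_min < _EPS:
        raise ComputationError(
            f"degenerate contour: intensity range is flat at {i_min:.2f} dB"
        )
    i_ref = i_min + cfg.ref_frac * (i_max - i_min)
    return i_min + cfg.threshold_frac * (i_ref - i_min)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive ``(first, last)`` index pairs of True runs in ``mask``."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for lo, hi in idx.reshape(-1, 2):
        runs.append((int(lo), int(hi) - 1))
    return runs


def _subtract_intervals(
    intervals: Sequence[Interval], cuts: Sequence[Interval]
) -> list[Interval]:
    out = list(intervals)
    for cut in cuts:
        nxt: list[Interval] = []
        for iv in out:
            if not iv.overlaps(cut):
                nxt.append(iv)
                continue
            if iv.start < cut.start:
                nxt.append(Interval(iv.start, cut.start))
            if cut.end < iv.end:
                nxt.append(Interval(cut.end, iv.end))
        out = nxt
    return sorted(out)


def _detect_runs(
    c: IntensityContour, cfg: SilenceConfig
) -> tuple[list[tuple[int, int]], Interval]:
    """Silence runs after merging/filtering/trimming, plus the trimmed span."""
    threshold = silence_threshold(c, cfg)
    below = c.values < threshold
    if below.all():
        raise ComputationError("no supra-threshold speech found in the contour")

    hop = c.hop_s
    win = c.window_s
    runs = _bool_runs(below)

    # A frame falls below threshold only when (nearly) its whole window is
    # silent, so a silence run of frames i..j extends over the full window
    # footprint [t_i - win/2, t_j + win/2]; run durations and inter-run
    # speech gaps are measured accordingly.

    # rule 2: absorb speech gaps shorter than min_speech_s
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) * hop - win < cfg.min_speech_s - _EPS:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    # rule 3: discard silences shorter than min_silence_s
    kept = [r for r in merged if (r[1] - r[0]) * hop + win >= cfg.min_silence_s - _EPS]

    # rule 4: trim silences touching the sample edges; the analysed span
    # runs from the first speech onset to the last speech offset
    span_lo = c.start
    span_hi = c.end
    if kept and kept[0][0] == 0:
        span_lo = c.times[kept[0][1]] + win / 2
        kept = kept[1:]
    if kept and kept[-1][1] == len(c) - 1:
        span_hi = c.times[kept[-1][0]] - win / 2
        kept = kept[:-1]
    return kept, Interval(span_lo, span_hi)


def detect_silences(
    c: IntensityContour,
    cfg: SilenceConfig = SilenceConfig(),
    exclusions: Sequence[Interval] = (),
) -> list[Interval]:
    """Detected silence intervals, sorted and non-overlapping.

    Boundary placement is frame-quantised: a silence run of frames
    ``i..j`` maps to its full window footprint ``[t_i - win/2, t_j +
    win/2)``, so boundaries carry up to one analysis window of blur
    relative to the true signal.
    """
    runs, _ = _detect_runs(c, cfg)
    half = c.window_s / 2
    intervals = [
        Interval(max(0.0, c.times[i] - half), c.times[j] + half) for i, j in runs
    ]
    if exclusions:
        intervals = _subtract_intervals(intervals, exclusions)
    return intervals


def silence_metrics(
    silences: Sequence[Interval],
    span: Interval,
    excluded_s: float = 0.0,
) -> SilenceMetrics:
    """Summarise silence intervals over an analysed span.

    ``pst`` is total silence time divided by the span duration (minus any
    excluded time).  With no silences, PST is 0 and median/MAD are left
    undefined (``None``).
    """
    denom = span.duration - excluded_s
    if denom <= 0:
        raise ValidationError("analysed span is empty after exclusions")
    durations = np.array([iv.duration for iv in silences], dtype=float)
    total = float(durations.sum())
    pst = min(1.0, total / denom)
    arcsin_pst = math.asin(math.sqrt(pst))
    if durations.size == 0:
        median_s: float | None = None
        mad_s: float | None = None
    else:
        median_s = float(np.median(durations))
        mad_s = float(np.median(np.abs(durations - median_s)))
    return SilenceMetrics(pst, arcsin_pst, median_s, mad_s, int(durations.size), span)


def analyze_waveform(
    w: Waveform,
    cfg: SilenceConfig = SilenceConfig(),
    *,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    floor_db: float = DEFAULT_FLOOR_DB,
    exclusions: Sequence[Interval] = (),
) -> tuple[SilenceMetrics, list[Interval]]:
    """Full silence analysis of a waveform: contour, detection, metrics."""
    c = intensity_contour(w, window_s=window_s, hop_s=hop_s, floor_db=floor_db)
    runs, span = _detect_runs(c, cfg)
    half = c.window_s / 2
    intervals = [
        Interval(max(0.0, c.times[i] - half), c.times[j] + half) for i, j in runs
    ]
    excluded_s = 0.0
    if exclusions:
        intervals = _subtract_intervals(intervals, exclusions)
        for cut in exclusions:
            hit = span.intersection(cut)
            if hit is not None:
                excluded_s += hit.duration
    return silence_metrics(intervals, span, excluded_s), intervals


def read_exclusions_csv(path) -> list[Interval]:
    """Read an exclusion mask CSV with columns ``start_s``, ``end_s``."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValidationError(f"exclusions CSV {path} is missing column {col!r}")
    out = []
    for row in df.itertuples(index=True):
        try:
            out.append(Interval(float(row.start_s), float(row.end_s)))
        except ValidationError as exc:
            raise ValidationError(f"exclusions CSV {path} row {row.Index}: {exc}") from exc
    return sorted(out)
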