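"""Synthetic audio and cohort generators with known ground truth.

Three generators make every pipeline stage testable without recordings:

* :func:`synth_audio` — speech/silence alternation with planted silence
  intervals (band-limited noise carrier; intensity, not spectral detail,
  carries the signal).
* :func:`synth_word` — two harmonic "vowel" segments with controllable
  durations and levels, returning the true vowel boundaries as a token.
* :func:`simulate_cohort` — per-group multivariate-normal feature draws
  whose default means/SDs are the published group summary statistics.

All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .errors import ValidationError
from .lexical_stress import WordToken
from .signal_core import Interval, Waveform

__all__ = [
    "SegmentSpec",
    "GroupSpec",
    "CohortSpec",
    "FEATURE_ORDER",
    "GROUP_FEATURE_DEFAULTS",
    "synth_audio",
    "synth_word",
    "simulate_cohort",
    "default_cohort_spec",
]

#: Default gap between speech level and the silence noise floor (dB).
FLOOR_DROP_DB = 40.0

#: Feature order used for cohort sampling.  PVI features are sampled on
#: the signed scale (weak-strong duration PVIs are negative) and emitted
#: as absolute values in the output table.
FEATURE_ORDER = [
    "arcsin_pst",
    "median_silence_s",
    "mad_silence_s",
    "pvi_dur_ws",
    "pvi_dur_sw",
    "pvi_int_ws",
    "pvi_int_sw",
]

_SIGNED_PVI = ("pvi_dur_ws", "pvi_dur_sw", "pvi_int_ws", "pvi_int_sw")

#: Published per-group feature means and SDs (silence durations in
#: seconds; proportion of silence time already arcsin-transformed; PVI
#: means on the signed scale).  Intensity-PVI moments were not published
#: (non-discriminative); plausible common values are used for all groups.
GROUP_FEATURE_DEFAULTS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "lvPPA": {
        "arcsin_pst": (0.61, 0.13),
        "median_silence_s": (0.1259, 0.0500),
        "mad_silence_s": (0.0865, 0.0477),
        "pvi_dur_ws": (-116.2, 18.3),
        "pvi_dur_sw": (89.6, 17.0),
        "pvi_int_ws": (-6.0, 3.0),
        "pvi_int_sw": (6.0, 3.0),
    },
    "nfvPPA": {
        "arcsin_pst": (0.62, 0.17),
        "median_silence_s": (0.2361, 0.2088),
        "mad_silence_s": (0.1586, 0.1259),
        "pvi_dur_ws": (-87.4, 26.9),
        "pvi_dur_sw": (63.9, 26.2),
        "pvi_int_ws": (-6.0, 3.0),
        "pvi_int_sw": (6.0, 3.0),
    },
    "control": {
        "arcsin_pst": (0.48, 0.09),
        "median_silence_s": (0.0833, 0.0272),
        "mad_silence_s": (0.0497, 0.0276),
        "pvi_dur_ws": (-109.7, 18.9),
        "pvi_dur_sw": (80.7, 16.0),
        "pvi_int_ws": (-6.0, 3.0),
        "pvi_int_sw": (6.0, 3.0),
    },
}


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of a synthetic passage: speech at a level, or silence."""

    kind: str
    duration_s: float
    level_db: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("speech", "silence"):
            raise ValidationError(f"segment kind must be 'speech' or 'silence', got {self.kind!r}")
        if self.duration_s <= 0:
            raise ValidationError(f"segment duration must be > 0, got {self.duration_s}")
        if self.kind == "speech" and self.level_db is None:
            raise ValidationError("speech segments need a level_db")


def _noise_at_level(rng: np.random.Generator, n: int, level_db: float, sos=None) -> np.ndarray:
    x = rng.standard_normal(n)
    if sos is not None and n > 24:
        x = spsig.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x * x))
    return x * (10.0 ** (level_db / 20.0) / rms)


def synth_audio(
    segments: Sequence[SegmentSpec],
    rate: float = 16000.0,
    seed: int = 0,
    floor_db: float | None = None,
) -> tuple[Waveform, list[Interval]]:
    """Synthesise a speech/silence passage and its planted silence truth.

    Speech segments are band-limited noise amplitude-set to their target
    RMS level; silence segments are noise at ``floor_db`` (default 40 dB
    below the quietest speech segment).  The spec must start and end with
    speech so that edge trimming is exercised separately.
    """
    segments = list(segments)
    if not segments:
        raise ValidationError("segment spec is empty")
    if segments[0].kind != "speech" or segments[-1].kind != "speech":
        raise ValidationError("segment spec must start and end with speech")
    levels = [s.level_db for s in segments if s.kind == "speech"]
    floor = min(levels) - FLOOR_DROP_DB if floor_db is None else floor_db
    if min(levels) - floor < 20.0:
        raise ValidationError(
            f"speech level must sit >= 20 dB above the silence floor ({floor} dB)"
        )
    rng = np.random.default_rng(seed)
    sos = spsig.butter(4, 0.35, output="sos")
    pieces: list[np.ndarray] = []
    truth: list[Interval] = []
    t = 0.0
    for seg in segments:
        n = int(round(seg.duration_s * rate))
        if seg.kind == "speech":
            pieces.append(_noise_at_level(rng, n, seg.level_db, sos))
        else:
            pieces.append(_noise_at_level(rng, n, floor))
            truth.append(Interval(t, t + n / rate))
        t += n / rate
    samples = np.concatenate(pieces)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples = samples / (peak * 1.001)
    return Waveform(samples, rate), truth


def _vowel(rng: np.random.Generator, n: int, rate: float, level_db: float, f0: float) -> np.ndarray:
    t = np.arange(n) / rate
    x = np.zeros(n)
    for k in range(1, 9):
        x += np.sin(2.0 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)) / k
    ramp = max(2, min(n // 4, int(0.005 * rate)))
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp)
    env[-ramp:] = np.linspace(1.0, 0.0, ramp)
    x *= env
    rms = np.sqrt(np.mean(x * x))
    return x * (10.0 ** (level_db / 20.0) / rms)


def synth_word(
    d1_ms: float,
    d2_ms: float,
    level1_db: float = -26.0,
    level2_db: float = -26.0,
    gap_ms: float = 60.0,
    rate: float = 16000.0,
    seed: int = 0,
    *,
    pad_ms: float = 80.0,
    f0: float = 120.0,
    word: str = "token",
    pattern: str | None = None,
) -> tuple[Waveform, WordToken]:
    """Synthesise a two-vowel word token with known vowel boundaries.

    Two harmonic segments at the target levels are separated by a
    floor-level gap and padded on both sides.  The returned token carries
    the true vowel intervals.  ``pattern`` defaults to SW when the first
    vowel is the longer one, else WS.
    """
    if d1_ms <= 0 or d2_ms <= 0 or gap_ms <= 0 or pad_ms <= 0:
        raise ValidationError("durations must be positive")
    rng = np.random.default_rng(seed)
    floor = min(level1_db, level2_db) - FLOOR_DROP_DB
    n_pad = int(round(pad_ms / 1000.0 * rate))
    n_gap = int(round(gap_ms / 1000.0 * rate))
    n1 = int(round(d1_ms / 1000.0 * rate))
    n2 = int(round(d2_ms / 1000.0 * rate))
    pieces = [
        _noise_at_level(rng, n_pad, floor),
        _vowel(rng, n1, rate, level1_db, f0),
        _noise_at_level(rng, n_gap, floor),
        _vowel(rng, n2, rate, level2_db, f0),
        _noise_at_level(rng, n_pad, floor),
    ]
    samples = np.concatenate(pieces)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples = samples / (peak * 1.001)
    v1_on = n_pad / rate
    v1_off = (n_pad + n1) / rate
    v2_on = (n_pad + n1 + n_gap) / rate
    v2_off = (n_pad + n1 + n_gap + n2) / rate
    if pattern is None:
        pattern = "SW" if d1_ms >= d2_ms else "WS"
    token = WordToken(word=word, pattern=pattern, v1=Interval(v1_on, v1_off), v2=Interval(v2_on, v2_off))
    return Waveform(samples, rate), token


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sample size and feature means/SDs (signed PVI scale)."""

    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"group n must be >= 0, got {self.n}")
        for feat in FEATURE_ORDER:
            if feat not in self.means or feat not in self.sds:
                raise ValidationError(f"group spec is missing feature {feat!r}")
            if self.sds[feat] < 0:
                raise ValidationError(f"SD for {feat!r} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort simulation spec: groups, optional shared correlation, seed."""

    groups: Mapping[str, GroupSpec]
    corr: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort spec has no groups")
        if self.corr is not None:
            corr = np.asarray(self.corr, dtype=float)
            k = len(FEATURE_ORDER)
            if corr.shape != (k, k):
                raise ValidationError(f"correlation matrix must be {k}x{k}")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValidationError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(corr).min() < -1e-8:
                raise ValidationError("correlation matrix must be positive semi-definite")
            object.__setattr__(self, "corr", corr)


def default_cohort_spec(
    n_lvppa: int = 21,
    n_nfvppa: int = 20,
    n_control: int = 17,
    seed: int | None = None,
) -> CohortSpec:
    """Cohort spec with the published group means/SDs as defaults."""
    sizes = {"lvPPA": n_lvppa, "nfvPPA": n_nfvppa, "control": n_control}
    groups = {
        name: GroupSpec(
            n=sizes[name],
            means={f: GROUP_FEATURE_DEFAULTS[name][f][0] for f in FEATURE_ORDER},
            sds={f: GROUP_FEATURE_DEFAULTS[name][f][1] for f in FEATURE_ORDER},
        )
        for name in sizes
        if sizes[name] > 0
    }
    return CohortSpec(groups=groups, seed=seed)


def simulate_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    *,
    abs_pvi: bool = True,
) -> pd.DataFrame:
    """Draw a subject-feature table from per-group normal distributions.

    Covariance is diagonal unless ``spec.corr`` supplies a shared
    correlation matrix.  PVI features are sampled on the signed scale and
    converted to absolute values unless ``abs_pvi=False``.  Draws in the
    distribution tails may produce negative silence durations; they are
    left unclipped so that sample moments remain unbiased.
    """
    if spec is None:
        spec = default_cohort_spec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    frames = []
    for name, group in spec.groups.items():
        mean = np.array([group.means[f] for f in FEATURE_ORDER])
        sds = np.array([group.sds[f] for f in FEATURE_ORDER])
        z = rng.standard_normal((group.n, len(FEATURE_ORDER)))
        if spec.corr is None:
            draws = mean + z * sds
        else:
            chol = np.linalg.cholesky(spec.corr + 1e-12 * np.eye(len(FEATURE_ORDER)))
            draws = mean + (z @ chol.T) * sds
        df = pd.DataFrame(draws, columns=FEATURE_ORDER)
        df.insert(0, "group", name)
        df.insert(0, "subject_id", [f"{name}_{i + 1:03d}" for i in range(group.n)])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if abs_pvi:
        for col in _SIGNED_PVI:
            out[col] = out[col].abs()
    cols = ["subject_id", "group", "arcsin_pst", "mad_silence_s", "median_silence_s",
            "pvi_dur_ws", "pvi_dur_sw", "pvi_int_ws", "pvi_int_sw"]
    return out[cols]
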