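"""Pairwise Variability Index (PVI) measures of lexical stress.

For each polysyllabic word token, the PVI quantifies the contrast between
the first two vowels:

    signed = 100 * (d1 - d2) / ((d1 + d2) / 2)

with ``d`` either vowel duration in ms or peak vowel intensity.  Values
near zero indicate equalised stress.  Word-level records are reduced to
per-subject medians, split by stress pattern (strong-weak vs weak-strong).

Peak intensities come from an uncalibrated dB-relative-to-full-scale
contour and can be negative, which would make the PVI ratio depend on the
dB reference; a fixed positive offset (default +96 dB) maps them onto a
positive pseudo-SPL scale before the ratio is taken.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal_core import (
    DEFAULT_FLOOR_DB,
    DEFAULT_HOP_S,
    DEFAULT_WINDOW_S,
    Interval,
    Waveform,
    intensity_contour,
    peak_db,
)
from .textgrid import read_textgrid

__all__ = [
    "SW_WORDS",
    "WS_WORDS",
    "WordToken",
    "PVIRecord",
    "StressProfile",
    "pvi",
    "word_pvi",
    "stress_profile",
    "read_vowel_annotations",
    "DB_OFFSET_DEFAULT",
]

#: Built-in strong-weak stimulus words (stress on the first syllable).
SW_WORDS = frozenset({"butterfly", "bicycle", "caterpillar", "dinosaur", "stethoscope"})
#: Built-in weak-strong stimulus words (stress on the second syllable).
WS_WORDS = frozenset({"banana", "computer", "pagoda", "potato", "thermometer"})

DB_OFFSET_DEFAULT = 96.0

_PATTERNS = ("SW", "WS")


@dataclass(frozen=True)
class WordToken:
    """A word token with its first two vowel intervals (seconds)."""

    word: str
    pattern: str
    v1: Interval
    v2: Interval

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValidationError(f"pattern must be one of {_PATTERNS}, got {self.pattern!r}")
        if self.v1.end > self.v2.start:
            raise ValidationError(
                f"{self.word}: first vowel [{self.v1.start}, {self.v1.end}) must precede "
                f"second vowel [{self.v2.start}, {self.v2.end})"
            )


@dataclass(frozen=True)
class PVIRecord:
    """Word-level PVI measurements (durations in ms, intensities in dB)."""

    word: str
    pattern: str
    d1_ms: float
    d2_ms: float
    peak1_db: float
    peak2_db: float
    pvi_dur_signed: float
    pvi_dur_abs: float
    pvi_int_signed: float
    pvi_int_abs: float

    def to_dict(self) -> dict:
        return {
            "word": self.word,
            "pattern": self.pattern,
            "d1_ms": self.d1_ms,
            "d2_ms": self.d2_ms,
            "pvi_dur_signed": self.pvi_dur_signed,
            "pvi_dur_abs": self.pvi_dur_abs,
            "peak1_db": self.peak1_db,
            "peak2_db": self.peak2_db,
            "pvi_int_signed": self.pvi_int_signed,
            "pvi_int_abs": self.pvi_int_abs,
        }


@dataclass(frozen=True)
class StressProfile:
    """Per-subject medians of word-level PVIs, split by stress pattern.

    Medians are ``None`` when no token of that pattern was seen.  Both
    the signed (reporting) and absolute (modelling) conventions are kept.
    """

    median_pvi_dur_ws_signed: float | None
    median_pvi_dur_sw_signed: float | None
    median_pvi_dur_ws_abs: float | None
    median_pvi_dur_sw_abs: float | None
    median_pvi_int_ws_signed: float | None
    median_pvi_int_sw_signed: float | None
    median_pvi_int_ws_abs: float | None
    median_pvi_int_sw_abs: float | None
    n_tokens_ws: int
    n_tokens_sw: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pvi(d1: float, d2: float) -> tuple[float, float]:
    """Pairwise Variability Index of two positive quantities.

    Returns ``(signed, absolute)`` where
    ``signed = 100 * (d1 - d2) / ((d1 + d2) / 2)``.  Scale-invariant and
    antisymmetric; ``|signed| < 200`` for all positive inputs.
    """
    if not (d1 > 0 and d2 > 0):
        raise ValidationError(f"pvi requires positive inputs, got d1={d1}, d2={d2}")
    signed = 100.0 * (d1 - d2) / ((d1 + d2) / 2.0)
    return signed, abs(signed)


def word_pvi(
    w: Waveform,
    token: WordToken,
    *,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    floor_db: float = DEFAULT_FLOOR_DB,
    db_offset: float = DB_OFFSET_DEFAULT,
) -> PVIRecord:
    """Duration and intensity PVIs of a word token measured on a waveform.

    Duration PVI uses the annotated vowel interval lengths in ms;
    intensity PVI uses peak contour values over each vowel, offset by
    ``db_offset`` onto a positive scale.
    """
    if token.v2.end > w.duration + 1e-9:
        raise ValidationError(
            f"{token.word}: vowel intervals extend to {token.v2.end:.3f} s but the "
            f"waveform is only {w.duration:.3f} s long"
        )
    c = intensity_contour(w, window_s=window_s, hop_s=hop_s, floor_db=floor_db)
    d1_ms = token.v1.duration * 1000.0
    d2_ms = token.v2.duration * 1000.0
    dur_signed, dur_abs = pvi(d1_ms, d2_ms)
    p1 = peak_db(c, token.v1)
    p2 = peak_db(c, token.v2)
    if p1 + db_offset <= 0 or p2 + db_offset <= 0:
        raise ValidationError(
            f"{token.word}: peak intensity below -{db_offset} dBFS; "
            "raise db_offset or check the recording level"
        )
    int_signed, int_abs = pvi(p1 + db_offset, p2 + db_offset)
    return PVIRecord(
        word=token.word,
        pattern=token.pattern,
        d1_ms=d1_ms,
        d2_ms=d2_ms,
        peak1_db=p1,
        peak2_db=p2,
        pvi_dur_signed=dur_signed,
        pvi_dur_abs=dur_abs,
        pvi_int_signed=int_signed,
        pvi_int_abs=int_abs,
    )


def _median(values: list[float]) -> float | None:
    return float(np.median(values)) if values else None


def stress_profile(records: Sequence[PVIRecord]) -> StressProfile:
    """Reduce word-level PVI records to per-pattern medians."""
    by_pattern: dict[str, list[PVIRecord]] = {"WS": [], "SW": []}
    for rec in records:
        by_pattern[rec.pattern].append(rec)
    ws, sw = by_pattern["WS"], by_pattern["SW"]
    return StressProfile(
        median_pvi_dur_ws_signed=_median([r.pvi_dur_signed for r in ws]),
        median_pvi_dur_sw_signed=_median([r.pvi_dur_signed for r in sw]),
        median_pvi_dur_ws_abs=_median([r.pvi_dur_abs for r in ws]),
        median_pvi_dur_sw_abs=_median([r.pvi_dur_abs for r in sw]),
        median_pvi_int_ws_signed=_median([r.pvi_int_signed for r in ws]),
        median_pvi_int_sw_signed=_median([r.pvi_int_signed for r in sw]),
        median_pvi_int_ws_abs=_median([r.pvi_int_abs for r in ws]),
        median_pvi_int_sw_abs=_median([r.pvi_int_abs for r in sw]),
        n_tokens_ws=len(ws),
        n_tokens_sw=len(sw),
    )


def _pattern_for_word(word: str, explicit: str | None, context: str) -> str:
    lowered = word.lower()
    if explicit:
        explicit = explicit.upper()
        if explicit not in _PATTERNS:
            raise ValidationError(f"{context}: unknown stress pattern {explicit!r}")
        return explicit
    if lowered in SW_WORDS:
        return "SW"
    if lowered in WS_WORDS:
        return "WS"
    raise ValidationError(
        f"{context}: word {word!r} is not in the built-in stimulus lists and no "
        "stress pattern was given"
    )


def _token(word: str, pattern: str | None, v1_on, v1_off, v2_on, v2_off, context: str) -> WordToken:
    try:
        v1 = Interval(float(v1_on), float(v1_off))
        v2 = Interval(float(v2_on), float(v2_off))
    except ValidationError as exc:
        raise ValidationError(f"{context}: {exc}") from exc
    return WordToken(word=word, pattern=_pattern_for_word(word, pattern, context), v1=v1, v2=v2)


def _read_annotation_csv(path) -> list[WordToken]:
    df = pd.read_csv(path)
    required = {"word", "v1_on_s", "v1_off_s", "v2_on_s", "v2_off_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation CSV {path} is missing columns {sorted(missing)}")
    tokens = []
    for row in df.itertuples(index=True):
        pattern = getattr(row, "pattern", None)
        if pattern is not None and (pd.isna(pattern) or str(pattern).strip() == ""):
            pattern = None
        tokens.append(
            _token(
                str(row.word),
                None if pattern is None else str(pattern),
                row.v1_on_s,
                row.v1_off_s,
                row.v2_on_s,
                row.v2_off_s,
                context=f"annotation CSV {path} row {row.Index}",
            )
        )
    return tokens


#: TextGrid interval labels: ``word_V1`` / ``word_V2``, with an optional
#: explicit pattern suffix for words outside the built-in lists,
#: e.g. ``zucchini_V1_WS``.
_LABEL_RE = re.compile(r"^(?P<word>.+?)_[Vv](?P<num>[12])(?:_(?P<pat>[SswW]{2}))?$")


def _read_annotation_textgrid(path, tier: str) -> list[WordToken]:
    tiers = read_textgrid(path)
    if tier not in tiers:
        raise ValidationError(
            f"tier {tier!r} not found in {path}; available: {sorted(tiers)}"
        )
    halves: dict[str, dict[str, tuple[float, float, str | None]]] = {}
    order: list[str] = []
    for iv in tiers[tier].intervals:
        label = iv.text.strip()
        if not label:
            continue
        m = _LABEL_RE.match(label)
        if not m:
            raise ValidationError(
                f"{path}: cannot parse interval label {label!r}; expected 'word_V1[_SW|_WS]'"
            )
        word = m.group("word")
        if word not in halves:
            halves[word] = {}
            order.append(word)
        halves[word][m.group("num")] = (iv.xmin, iv.xmax, m.group("pat"))
    tokens = []
    for word in order:
        parts = halves[word]
        if set(parts) != {"1", "2"}:
            raise ValidationError(f"{path}: word {word!r} does not have exactly V1 and V2 intervals")
        v1_on, v1_off, pat1 = parts["1"]
        v2_on, v2_off, pat2 = parts["2"]
        tokens.append(
            _token(word, pat1 or pat2, v1_on, v1_off, v2_on, v2_off, context=f"{path}:{word}")
        )
    return tokens


def read_vowel_annotations(path, tier: str = "vowels") -> list[WordToken]:
    """Read vowel-boundary annotations from a CSV or Praat TextGrid.

    CSV columns: ``word, pattern, v1_on_s, v1_off_s, v2_on_s, v2_off_s``
    (``pattern`` may be blank for the built-in stimulus words).  TextGrid
    input needs an interval tier (default name ``"vowels"``) with labels
    ``word_V1`` / ``word_V2``.
    """
    path_str = os.fspath(path)
    if path_str.lower().endswith(".csv"):
        return _read_annotation_csv(path_str)
    return _read_annotation_textgrid(path_str, tier)


def records_to_dataframe(records: Iterable[PVIRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
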