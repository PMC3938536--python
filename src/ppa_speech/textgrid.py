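"""Minimal Praat TextGrid reader/writer for interval tiers.

Supports both the long ("full") and short text forms.  Point tiers are
ignored.  Only what the annotation workflow needs: named interval tiers
holding ``(xmin, xmax, text)`` triples.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["TGInterval", "TGTier", "read_textgrid", "write_textgrid"]


@dataclass(frozen=True)
class TGInterval:
    xmin: float
    xmax: float
    text: str


@dataclass
class TGTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[TGInterval] = field(default_factory=list)


def _unquote(s: str) -> str:
    s = s.strip()
    if s.startswith('"') and s.endswith('"') and len(s) >= 2:
        s = s[1:-1]
    return s.replace('""', '"')


def read_textgrid(path) -> dict[str, TGTier]:
    """Parse a TextGrid file into ``{tier_name: TGTier}``."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ValidationError(f"TextGrid file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise ValidationError(f"{path} does not look like a Praat TextGrid")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if any("=" in ln for ln in lines[2:]):
        tiers = _parse_long(lines, path)
    else:
        tiers = _parse_short(lines, path)
    return {t.name: t for t in tiers}


def _parse_long(lines: list[str], path: str) -> list[TGTier]:
    tiers: list[TGTier] = []
    cur: TGTier | None = None
    pending: dict[str, float | str] = {}
    in_interval = False
    kv = re.compile(r"^([A-Za-z]+)\s*(?:\[\d*\]\s*)?=\s*(.*)$")
    for ln in lines:
        if re.match(r"^intervals\s*\[\d+\]", ln):
            _flush_interval(cur, pending, in_interval)
            pending = {}
            in_interval = cur is not None
            continue
        m = kv.match(ln)
        if not m:
            continue
        key, raw = m.group(1), m.group(2).strip()
        if key == "class":
            _flush_interval(cur, pending, in_interval)
            pending, in_interval = {}, False
            if _unquote(raw) == "IntervalTier":
                cur = TGTier(name="", xmin=0.0, xmax=0.0)
                tiers.append(cur)
            else:
                cur = None
        elif key == "name" and cur is not None and not in_interval:
            cur.name = _unquote(raw)
        elif key in ("xmin", "xmax"):
            val = float(raw)
            if in_interval:
                pending[key] = val
            elif cur is not None:
                setattr(cur, key, val)
        elif key == "text" and in_interval:
            pending["text"] = _unquote(raw)
    _flush_interval(cur, pending, in_interval)
    if not tiers:
        raise ValidationError(f"no interval tiers found in {path}")
    return tiers


def _flush_interval(cur: TGTier | None, pending: dict, in_interval: bool) -> None:
    if cur is not None and in_interval and {"xmin", "xmax"} <= pending.keys():
        cur.intervals.append(
            TGInterval(float(pending["xmin"]), float(pending["xmax"]), str(pending.get("text", "")))
        )


def _parse_short(lines: list[str], path: str) -> list[TGTier]:
    # header: "ooTextFile", "TextGrid", xmin, xmax, <exists>, ntiers
    vals = lines[2:]
    try:
        i = 3  # skip global xmin, xmax, <exists>
        n_tiers = int(vals[i]); i += 1
        tiers: list[TGTier] = []
        for _ in range(n_tiers):
            klass = _unquote(vals[i]); i += 1
            name = _unquote(vals[i]); i += 1
            xmin = float(vals[i]); xmax = float(vals[i + 1]); i += 2
            n_items = int(vals[i]); i += 1
            if klass == "IntervalTier":
                tier = TGTier(name, xmin, xmax)
                for _ in range(n_items):
                    tier.intervals.append(
                        TGInterval(float(vals[i]), float(vals[i + 1]), _unquote(vals[i + 2]))
                    )
                    i += 3
                tiers.append(tier)
            else:  # point tier: number, mark
                i += 2 * n_items
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"malformed short-form TextGrid {path}: {exc}") from exc
    if not tiers:
        raise ValidationError(f"no interval tiers found in {path}")
    return tiers


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid(path, tiers: list[TGTier]) -> None:
    """Write interval tiers as a long-form TextGrid."""
    if not tiers:
        raise ValidationError("cannot write a TextGrid with no tiers")
    xmin = min(t.xmin for t in tiers)
    xmax = max(t.xmax for t in tiers)
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(tiers, start=1):
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f"        name = {_quote(tier.name)}",
            f"        xmin = {tier.xmin}",
            f"        xmax = {tier.xmax}",
            f"        intervals: size = {len(tier.intervals)}",
        ]
        for ii, iv in enumerate(tier.intervals, start=1):
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {iv.xmin}",
                f"            xmax = {iv.xmax}",
                f"            text = {_quote(iv.text)}",
            ]
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")
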