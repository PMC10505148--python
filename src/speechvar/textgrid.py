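"""Minimal Praat TextGrid (long text format) reader and writer.

Only interval tiers are read; point tiers are skipped.  Files are decoded
as UTF-8, falling back to UTF-16 when a byte-order mark is present (Praat
writes UTF-16 by default on some platforms).  Times round-trip at full
float precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError

_RE_KV = re.compile(r'^\s*([A-Za-z?][\w? ]*?)\s*=\s*(.*?)\s*$')
_RE_ITEM = re.compile(r'^\s*item\s*\[\s*(\d*)\s*\]\s*:?\s*$')
_RE_INTERVAL = re.compile(r'^\s*intervals\s*\[\s*(\d+)\s*\]\s*:?\s*$')
_RE_POINT = re.compile(r'^\s*points\s*\[\s*(\d+)\s*\]\s*:?\s*$')
_RE_SIZE = re.compile(r'^\s*(intervals|points)\s*:\s*size\s*=\s*(\d+)\s*$')


@dataclass
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass
class Tier:
    name: str
    xmin: float
    xmax: float
    tier_class: str = "IntervalTier"
    intervals: list[Interval] = field(default_factory=list)


@dataclass
class TextGrid:
    xmin: float
    xmax: float
    tiers: list[Tier] = field(default_factory=list)

    def tier(self, name: str) -> Tier | None:
        for t in self.tiers:
            if t.name == name:
                return t
        return None


def _decode(path: Path) -> str:
    raw = path.read_bytes()
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8")


def _unquote(value: str) -> str:
    value = value.strip()
    if value.startswith('"') and value.endswith('"') and len(value) >= 2:
        # Praat escapes embedded quotes by doubling them
        return value[1:-1].replace('""', '"')
    return value


def read_textgrid_file(path: str | Path) -> TextGrid:
    """Parse a long-format TextGrid; raise ParseError naming the bad line."""
    path = Path(path)
    lines = _decode(path).splitlines()

    def fail(lineno: int, msg: str) -> ParseError:
        return ParseError(f"{path.name}:{lineno + 1}: {msg}")

    def to_float(lineno: int, value: str, what: str) -> float:
        try:
            return float(value)
        except ValueError:
            raise fail(lineno, f"non-numeric {what}: {value!r}") from None

    header: dict[str, str] = {}
    grid: TextGrid | None = None
    tier: Tier | None = None
    tier_kv: dict[str, str] | None = None
    interval: dict[str, str] | None = None
    interval_line = 0

    def flush_tier_header(lineno: int) -> None:
        """Materialise the pending tier once its header lines are complete."""
        nonlocal tier, tier_kv
        if tier_kv is None or tier is not None:
            return
        assert grid is not None
        tier = Tier(
            name=_unquote(tier_kv.get("name", "")),
            xmin=to_float(lineno, tier_kv.get("xmin", str(grid.xmin)), "tier xmin"),
            xmax=to_float(lineno, tier_kv.get("xmax", str(grid.xmax)), "tier xmax"),
            tier_class=_unquote(tier_kv.get("class", "IntervalTier")),
        )
        grid.tiers.append(tier)

    def flush_interval(lineno: int) -> None:
        nonlocal interval
        if interval is None:
            return
        if tier is not None and tier.tier_class != "IntervalTier":
            interval = None  # point-tier entry: skipped
            return
        if "xmin" not in interval or "xmax" not in interval:
            raise fail(interval_line, "interval lacks xmin/xmax")
        assert tier is not None
        tier.intervals.append(
            Interval(
                to_float(lineno, interval["xmin"], "interval xmin"),
                to_float(lineno, interval["xmax"], "interval xmax"),
                _unquote(interval.get("text", "")),
            )
        )
        interval = None

    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("tiers?"):
            continue

        m = _RE_ITEM.match(stripped)
        if m is not None:
            flush_interval(i)
            if m.group(1) == "":
                # 'item []:' opens the tier list
                if grid is not None:
                    raise fail(i, "duplicate 'item []:' block")
                grid = TextGrid(
                    to_float(i, header.get("xmin", "0"), "xmin"),
                    to_float(i, header.get("xmax", "0"), "xmax"),
                )
            else:
                if grid is None:
                    raise fail(i, "tier before 'item []:' block")
                tier = None
                tier_kv = {}
            continue

        if _RE_SIZE.match(stripped):
            flush_tier_header(i)
            continue

        m = _RE_INTERVAL.match(stripped) or _RE_POINT.match(stripped)
        if m is not None:
            flush_interval(i)
            flush_tier_header(i)
            interval = {}
            interval_line = i
            continue

        m = _RE_KV.match(stripped)
        if m is None:
            raise fail(i, f"unparseable line: {stripped!r}")
        key, value = m.group(1), m.group(2)
        if interval is not None:
            interval[key] = value
        elif tier_kv is not None and tier is None:
            tier_kv[key] = value
        else:
            header[key] = value

    flush_interval(len(lines))
    if grid is None:
        raise ParseError(f"{path.name}: not a long-format TextGrid (no 'item []:' block)")
    # drop point-tier contents: they carry no intervals by construction
    for t in grid.tiers:
        if t.tier_class != "IntervalTier":
            t.intervals = []
    return grid


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(x))


def write_textgrid_file(grid: TextGrid, path: str | Path) -> None:
    """Write a long-format TextGrid (UTF-8)."""
    out: list[str] = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {_fmt(grid.xmin)}",
        f"xmax = {_fmt(grid.xmax)}",
        "tiers? <exists>",
        f"size = {len(grid.tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(grid.tiers, start=1):
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier.name}"',
            f"        xmin = {_fmt(tier.xmin)}",
            f"        xmax = {_fmt(tier.xmax)}",
            f"        intervals: size = {len(tier.intervals)}",
        ]
        for ii, iv in enumerate(tier.intervals, start=1):
            text = iv.text.replace('"', '""')
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {_fmt(iv.xmin)}",
                f"            xmax = {_fmt(iv.xmax)}",
                f'            text = "{text}"',
            ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
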