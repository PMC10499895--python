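"""Overlap of breakpoints with annotation interval tracks (repeats, cRSS).

Tracks are lists of 1-based inclusive intervals matching the catalog's
coordinate convention; strict BED (0-based half-open) can be converted on
import. Position classification supports a symmetric vicinity margin
(the +/-30 bp cryptic-RSS rule) and an asymmetric one (0 bp upstream /
N bp downstream) for the looser "in or immediately 3' of a repeat" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .catalog import IntronSpace
from .clusters import percent

__all__ = [
    "AnnotationInterval",
    "Vicinity",
    "classify_position",
    "fraction_overlapping",
    "track_coverage",
    "load_track",
]

CATEGORIES = ("repeat", "cRSS", "other")


@dataclass(frozen=True)
class AnnotationInterval:
    start: int
    end: int
    category: str = "other"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval {self.name!r}: end < start")
        if self.category not in CATEGORIES:
            raise ValueError(f"interval {self.name!r}: category {self.category!r}")


@dataclass(frozen=True)
class Vicinity:
    """Margin around an interval: ``upstream`` 5' of start, ``downstream`` 3' of end."""

    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("vicinity margins must be >= 0")

    @classmethod
    def coerce(cls, v: "int | Vicinity") -> "Vicinity":
        if isinstance(v, Vicinity):
            return v
        return cls(upstream=int(v), downstream=int(v))


def classify_position(position: int,
                      track: Sequence[AnnotationInterval],
                      vicinity: int | Vicinity = 30) -> tuple[str, list[AnnotationInterval]]:
    """Classify a position as inside / vicinity / outside a track.

    "inside" wins over "vicinity"; all matched intervals are returned.
    """
    vic = Vicinity.coerce(vicinity)
    inside = [iv for iv in track if iv.start <= position <= iv.end]
    if inside:
        return "inside", inside
    near = [iv for iv in track
            if iv.start - vic.upstream <= position < iv.start
            or iv.end < position <= iv.end + vic.downstream]
    if near:
        return "vicinity", near
    return "outside", []


def fraction_overlapping(positions: Sequence[int],
                         track: Sequence[AnnotationInterval],
                         vicinity: int | Vicinity = 30) -> tuple[int, float]:
    """Count positions inside or in the vicinity of the track, with percentage
    (one decimal, half-away-from-zero)."""
    if not positions:
        raise ValueError("positions must be non-empty")
    count = sum(classify_position(p, track, vicinity)[0] != "outside" for p in positions)
    return count, percent(count, len(positions), 1)


def track_coverage(track: Sequence[AnnotationInterval], space: IntronSpace) -> tuple[int, float]:
    """Base pairs covered by the (merged) track and percentage of the intron."""
    for iv in track:
        if iv.start < 1 or iv.end > space.length:
            raise ValueError(f"interval {iv.name!r} [{iv.start},{iv.end}] outside {space.name}")
    covered = 0
    cur_start = cur_end = None
    for iv in sorted(track, key=lambda iv: (iv.start, iv.end)):
        if cur_end is None:
            cur_start, cur_end = iv.start, iv.end
        elif iv.start <= cur_end + 1:
            cur_end = max(cur_end, iv.end)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = iv.start, iv.end
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered, percent(covered, space.length, 1)


def load_track(path: str | Path, category: str = "other",
               strict_bed: bool = False) -> list[AnnotationInterval]:
    """Read an interval track.

    Default format: tab-separated ``start  end  [name]  [category]`` with
    1-based inclusive coordinates; ``strict_bed=True`` interprets columns as
    BED ``chrom  start  end  [name]`` (0-based half-open) and converts.
    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    intervals: list[AnnotationInterval] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if strict_bed:
            start, end = int(fields[1]) + 1, int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            cat = category
        else:
            start, end = int(fields[0]), int(fields[1])
            name = fields[2] if len(fields) > 2 else ""
            cat = fields[3] if len(fields) > 3 else category
        intervals.append(AnnotationInterval(start=start, end=end, category=cat, name=name))
    return intervals
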