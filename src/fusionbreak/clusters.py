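"""Breakpoint clustering statistics.

Three complementary views: maximum-coverage sliding window (used for the
40-bp hotspot), membership counts over fixed configured regions (used for
the two large downstream clusters), and gap-based agglomeration as an
exploratory alternative that needs no preset bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .catalog import Breakpoint

__all__ = [
    "Region",
    "WindowResult",
    "RegionCounts",
    "max_coverage_window",
    "count_in_regions",
    "percent",
    "max_gap_clusters",
]


@dataclass(frozen=True)
class Region:
    """A closed interval of intron-relative coordinates."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.label!r}: end < start")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class WindowResult:
    window_start: int
    width: int
    count: int
    member_indices: tuple[int, ...]

    @property
    def window_end(self) -> int:
        return self.window_start + self.width - 1


def max_coverage_window(positions: Sequence[int], width: int) -> WindowResult:
    """Find the width-bp window covering the most positions.

    The returned window is the smallest start ``s >= 1`` such that no other
    window of the same width covers more positions. ``member_indices`` are
    indices into the input sequence, so callers can recover attributes of
    the covered break events.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    if width < 1:
        raise ValueError("width must be >= 1")
    # Coverage as a function of window start only changes at s = p - width + 1
    # (a position enters) so the optimum is attained at one of those starts.
    candidates = sorted({max(1, p - width + 1) for p in positions})
    best: WindowResult | None = None
    for s in candidates:
        members = tuple(i for i, p in enumerate(positions) if s <= p <= s + width - 1)
        if best is None or len(members) > best.count:
            best = WindowResult(window_start=s, width=width,
                                count=len(members), member_indices=members)
    assert best is not None
    return best


@dataclass(frozen=True)
class RegionCounts:
    """Per-region and outside membership, split by orientation."""

    by_region: dict
    outside: dict

    def total(self) -> int:
        return sum(sum(v.values()) for v in self.by_region.values()) + sum(self.outside.values())


def count_in_regions(breaks: Sequence[Breakpoint], regions: Sequence[Region]) -> RegionCounts:
    """Count breakpoints per region (inclusive of endpoints) and outside.

    Regions must be pairwise non-overlapping so the counts partition the
    input.
    """
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"overlapping regions {a.label!r} and {b.label!r}")

    def empty() -> dict:
        return {"TCF3::PBX1": 0, "PBX1::TCF3": 0}

    by_region = {r.label or f"{r.start}-{r.end}": empty() for r in regions}
    outside = empty()
    labels = [r.label or f"{r.start}-{r.end}" for r in regions]
    for bp in breaks:
        for region, label in zip(regions, labels):
            if bp.position in region:
                by_region[label][bp.orientation] += 1
                break
        else:
            outside[bp.orientation] += 1
    return RegionCounts(by_region=by_region, outside=outside)


def percent(count: int, total: int, decimals: int = 0) -> float:
    """100*count/total, rounded half-away-from-zero to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must be within 0..total")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def max_gap_clusters(positions: Sequence[int], max_gap: int) -> list[tuple[int, int, int]]:
    """Single-linkage clustering: positions within ``max_gap`` share a cluster.

    Returns ``(start, end, count)`` triples ordered by start. Duplicate
    positions are counted once per occurrence.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not positions:
        return []
    ordered = sorted(positions)
    clusters: list[tuple[int, int, int]] = []
    start = prev = ordered[0]
    count = 1
    for p in ordered[1:]:
        if p - prev <= max_gap:
            count += 1
        else:
            clusters.append((start, prev, count))
            start, count = p, 1
        prev = p
    clusters.append((start, prev, count))
    return clusters
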