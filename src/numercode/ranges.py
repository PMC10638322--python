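"""Emergent number ranges: minimal cover of 1..50 by monotonic regions.

No single inhibition strength encodes every numerosity: strong inhibition
is monotone only over the first few set sizes, weak inhibition only over
the large ones.  Selecting the smallest set of strengths whose monotonic
regions jointly cover the target range partitions it into contiguous
intervals — the model's account of the behavioural breakpoints between
the subitizing, estimation and large-number ranges.

The instance is tiny (at most 15 regions), so the cover is found by exact
exhaustive search, lexicographically optimising

1. number of target points covered (the published partition itself has a
   small uncovered gap, so full coverage cannot be demanded),
2. number of strengths used (fewer is better),
3. total region length (prefer the longest, most informative regions),
4. larger strengths on lower intervals (deterministic final tie-break).

Overlaps between chosen regions are cut at the midpoint of the overlap,
with the odd point going to the lower-strength region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import List, Sequence, Tuple

from .encoding import MonotonicRegion

__all__ = ["RangeCover", "minimal_cover"]


@dataclass
class RangeCover:
    """Chosen inhibition strengths with their disjoint assigned intervals."""

    chosen: List[Tuple[float, Tuple[int, int]]]  # (beta, (n_lo, n_hi)), sorted by interval
    uncovered: List[int]
    target: Tuple[int, int]

    @property
    def n_strengths(self) -> int:
        return len(self.chosen)

    @property
    def betas(self) -> Tuple[float, ...]:
        return tuple(b for b, _ in self.chosen)

    def interval_of(self, beta: float) -> Tuple[int, int]:
        for b, iv in self.chosen:
            if abs(b - beta) <= 1e-9:
                return iv
        raise KeyError(f"beta {beta} not among chosen strengths {self.betas}")

    def to_dict(self) -> dict:
        return {
            "target": list(self.target),
            "chosen": [
                {"beta": b, "n_lo": iv[0], "n_hi": iv[1]} for b, iv in self.chosen
            ],
            "uncovered": self.uncovered,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _coverage_mask(region: MonotonicRegion, lo: int, hi: int) -> int:
    lo_c = max(region.n_lo, lo)
    hi_c = min(region.n_hi, hi)
    if lo_c > hi_c:
        return 0
    width = hi_c - lo_c + 1
    return ((1 << width) - 1) << (lo_c - lo)


def _assign_intervals(
    regions: Sequence[MonotonicRegion], lo: int, hi: int
) -> List[Tuple[float, Tuple[int, int]]]:
    """Cut overlapping regions into disjoint intervals (midpoint rule)."""
    ordered = sorted(regions, key=lambda r: (r.n_lo, r.n_hi))
    bounds = [[max(r.n_lo, lo), min(r.n_hi, hi)] for r in ordered]
    for i in range(len(ordered) - 1):
        a, b = bounds[i], bounds[i + 1]
        if b[0] <= a[1]:  # overlap
            o_lo, o_hi = b[0], min(a[1], b[1])
            total = o_lo + o_hi
            if total % 2:
                cut = total // 2
            else:
                mid = total // 2
                # tie point goes to the lower-beta region
                cut = mid if ordered[i].beta < ordered[i + 1].beta else mid - 1
            a[1] = min(a[1], cut)
            b[0] = cut + 1
    return [
        (r.beta, (int(b[0]), int(b[1])))
        for r, b in zip(ordered, bounds)
        if b[0] <= b[1]
    ]


def minimal_cover(
    regions: Sequence[MonotonicRegion],
    target: Tuple[int, int] = (1, 50),
) -> RangeCover:
    """Exact minimal cover of the target set-size interval.

    Exhaustively scores every subset of regions by
    ``(covered points, -subset size, total region length, strengths on
    lower intervals)`` and assigns disjoint sub-intervals to the winner.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("minimal_cover: no regions supplied")
    lo, hi = int(target[0]), int(target[1])
    if lo > hi:
        raise ValueError("empty target interval")

    masks = [_coverage_mask(r, lo, hi) for r in regions]
    best = None
    best_key = None
    for size in range(1, len(regions) + 1):
        for subset in combinations(range(len(regions)), size):
            mask = 0
            for i in subset:
                mask |= masks[i]
            covered = mask.bit_count()
            total_len = sum(regions[i].length for i in subset)
            low_pref = tuple(
                r.beta
                for r in sorted(
                    (regions[i] for i in subset), key=lambda r: (r.n_lo, r.n_hi)
                )
            )
            key = (covered, -size, total_len, low_pref)
            if best_key is None or key > best_key:
                best_key = key
                best = subset
        if best is not None and best_key[0] == hi - lo + 1 and -best_key[1] <= size:
            # full coverage found at this cardinality; larger subsets
            # cannot improve the lexicographic key
            break

    chosen_regions = [regions[i] for i in best]
    assigned = _assign_intervals(chosen_regions, lo, hi)
    covered_pts = set()
    for _, (a, b) in assigned:
        covered_pts.update(range(a, b + 1))
    uncovered = [n for n in range(lo, hi + 1) if n not in covered_pts]
    return RangeCover(chosen=assigned, uncovered=uncovered, target=(lo, hi))
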