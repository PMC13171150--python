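"""Interval algebra on 0-based half-open genomic intervals.

All functions operate on lists of ``(chrom, start, end)`` tuples with
``start < end``. Outputs are sorted by ``(chrom, start)`` and, where the
operation guarantees it, pairwise disjoint.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, List, Tuple

Interval = Tuple[str, int, int]


def _by_chrom(ivs: Iterable[Interval]) -> dict:
    out: dict = defaultdict(list)
    for chrom, start, end in ivs:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        out[chrom].append((start, end))
    for chrom in out:
        out[chrom].sort()
    return out


def merge(ivs: Iterable[Interval], gap: int = 0) -> List[Interval]:
    """Union-merge intervals; intervals closer than ``gap`` bp are joined.

    ``gap=0`` merges overlapping or book-ended intervals.
    """
    grouped = _by_chrom(ivs)
    out: List[Interval] = []
    for chrom in sorted(grouped):
        cur_s, cur_e = None, None
        for s, e in grouped[chrom]:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (each is union-merged first)."""
    am, bm = _by_chrom(merge(a)), _by_chrom(merge(b))
    out: List[Interval] = []
    for chrom in sorted(set(am) & set(bm)):
        i = j = 0
        xs, ys = am[chrom], bm[chrom]
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append((chrom, s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Parts of ``a`` not covered by ``b`` (both union-merged first)."""
    am, bm = _by_chrom(merge(a)), _by_chrom(merge(b))
    out: List[Interval] = []
    for chrom in sorted(am):
        cuts = bm.get(chrom, [])
        for s, e in am[chrom]:
            pos = s
            for cs, ce in cuts:
                if ce <= pos or cs >= e:
                    continue
                if cs > pos:
                    out.append((chrom, pos, cs))
                pos = max(pos, ce)
                if pos >= e:
                    break
            if pos < e:
                out.append((chrom, pos, e))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    """Total bp covered (intervals are merged first, so overlap counts once)."""
    return sum(e - s for _, s, e in merge(ivs))


def coverage_intervals(
    ivs_per_unit: Iterable[Iterable[Interval]],
) -> List[Tuple[str, int, int, int]]:
    """Breakpoint sweep: maximal intervals with a constant number of
    covering units. Each unit's intervals are merged first so a unit
    counts at most once per base. Returns ``(chrom, start, end, count)``
    with count >= 1.
    """
    events: dict = defaultdict(list)
    for unit in ivs_per_unit:
        for chrom, s, e in merge(unit):
            events[chrom].append((s, 1))
            events[chrom].append((e, -1))
    out: List[Tuple[str, int, int, int]] = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        depth = 0
        prev = None
        for pos, delta in pts:
            if prev is not None and pos > prev and depth > 0:
                if out and out[-1][0] == chrom and out[-1][2] == prev and out[-1][3] == depth:
                    out[-1] = (chrom, out[-1][1], pos, depth)
                else:
                    out.append((chrom, prev, pos, depth))
            depth += delta
            prev = pos
    return out
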