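"""Half-open interval arithmetic on a single chromosome.

Intervals are (start, end) tuples with start < end.  Used for domain
merging, replicate intersection, similarity scoring and enrichment.
"""

from __future__ import annotations


def merge(intervals, gap: int = 0) -> list[tuple[int, int]]:
    """Union-merge; intervals closer than ``gap`` (default: touching) coalesce."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def intersect(a, b) -> list[tuple[int, int]]:
    """Intersection of two merged interval lists (linear sweep)."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets) -> list[tuple[int, int]]:
    sets = list(sets)
    if not sets:
        return []
    acc = merge(sets[0])
    for s in sets[1:]:
        acc = intersect(acc, s)
    return acc


def total_bp(intervals) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlap_bp(a, b) -> int:
    return total_bp(intersect(a, b))
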