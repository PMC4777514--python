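"""Adaptive, overlapping analysis windows.

4C-Seq coverage falls off steeply with genomic distance from the bait,
so fixed-size windows either drown the near-bait region or starve
far-cis and trans.  Window sizes here adapt to local coverage: at each
observed fragment the size is the linear distance to the k-th nearest
observed fragment, a smoothing spline turns those sizes into a
continuous per-chromosome size function shared by the whole dataset,
and overlapping windows are chained so that each window starts at the
midpoint of its predecessor.  Overlap halves the step size and sharpens
domain borders.

Default k per analysis mode: 5 near the bait, 10 for the whole cis
chromosome, 15 in trans for 6bp cutters and 100 for 4bp cutters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

DEFAULT_K = {"nearbait": 5, "cis": 10, "trans_6bp": 15, "trans_4bp": 100}
NEARBAIT_SPAN = {"6bp": 10_000_000, "4bp": 2_000_000}


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    index: int
    side: str          # 'left' | 'right' | 'trans'

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowSet:
    """Ordered overlapping windows for one chromosome and analysis mode."""

    chrom: str
    windows: list[Window]
    mode: str                      # 'nearbait' | 'cis' | 'trans'
    k: int
    bait_pos: int | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def side(self, side: str) -> list[Window]:
        return [w for w in self.windows if w.side == side]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for w in self.windows:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\tw{w.index}:{w.side}\n")


class SizeProfile:
    """Smooth positive map from chromosome position to window size (bp).

    Fitted as a cubic smoothing spline through (anchor, k-NN size)
    pairs; evaluations are clamped to the anchor range and floored at
    the minimum observed fragment spacing so sizes stay positive.
    """

    MAX_FIT_ANCHORS = 1000

    def __init__(self, chrom: str, anchors, sizes, smoothing: float | None = None,
                 min_size: float | None = None):
        anchors = np.asarray(anchors, dtype=float)
        sizes = np.asarray(sizes, dtype=float)
        if anchors.shape != sizes.shape or anchors.ndim != 1:
            raise ValueError("anchors and sizes must be 1-D and of equal length")
        if (sizes <= 0).any():
            raise ValueError("window sizes must be positive")
        order = np.argsort(anchors)
        anchors, sizes = anchors[order], sizes[order]
        # pool duplicate anchor positions (same fragment across samples)
        uniq, inv = np.unique(anchors, return_inverse=True)
        pooled = np.zeros(len(uniq))
        np.add.at(pooled, inv, sizes)
        pooled /= np.bincount(inv)

        self.chrom = chrom
        self.anchors = uniq
        self.sizes = pooled
        # the fitted function may not dip below the smallest size actually
        # observed: an undershooting spline would otherwise shatter sparse
        # stretches into sub-fragment windows
        self.min_size = float(min_size) if min_size is not None else float(sizes.min())
        self.min_size = max(self.min_size, 2.0)   # window must be splittable

        # fit on count-balanced bins: cheap, and pre-averaging stabilizes the
        # generalized cross-validation choice of the roughness penalty
        if len(uniq) > self.MAX_FIT_ANCHORS:
            edges = np.linspace(0, len(uniq), self.MAX_FIT_ANCHORS + 1).astype(int)
            fx = np.array([uniq[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
            fy = np.array([pooled[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
        else:
            fx, fy = uniq, pooled

        if len(fx) < 5:   # below the smoothing-spline minimum
            warnings.warn("fewer than 5 anchors; falling back to linear interpolation",
                          stacklevel=2)
            self._fn = lambda x: np.interp(x, fx, fy)
        else:
            lam = None if smoothing is None else smoothing
            spline = make_smoothing_spline(fx, fy, lam=lam)
            self._fn = spline
        self._fit_anchors = fx

    def __call__(self, pos) -> np.ndarray | float:
        pos = np.clip(np.asarray(pos, dtype=float), self.anchors[0], self.anchors[-1])
        val = np.maximum(np.asarray(self._fn(pos), dtype=float), self.min_size)
        return float(val) if val.ndim == 0 else val


def knn_sizes(observed_positions, k: int) -> np.ndarray:
    """Distance from each observed fragment to the k-th observed fragment
    downstream of it.

    A window of this size anchored at the fragment therefore contains
    exactly k further observed fragments, which is what keeps the signal
    per window comparable across coverage regimes; in real 4C data
    observed fragments arrive as flank pairs around each cut site, so a
    symmetric nearest-distance rule would routinely span fewer than k
    informative positions.  Fragments within k of the chromosome end use
    the mirrored upstream distance.  Requires at least k+1 observed
    fragments.
    """
    pos = np.asarray(observed_positions, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pos) < k + 1:
        raise ValueError(
            f"need at least {k + 1} observed fragments for k={k}; got {len(pos)}. "
            "Use a larger region or a smaller k."
        )
    pos = np.sort(pos)
    n = len(pos)
    out = np.empty(n)
    for i in range(n):
        if i + k < n:
            out[i] = pos[i + k] - pos[i]
        else:
            out[i] = pos[i] - pos[i - k]
    return np.maximum(out, 1.0)


def fit_size_profile(anchors, sizes, chrom: str = "chr", smoothing: float | None = None,
                     min_size: float | None = None) -> SizeProfile:
    """Fit the per-chromosome size function to (position, k-NN size) pairs."""
    return SizeProfile(chrom, anchors, sizes, smoothing=smoothing, min_size=min_size)


def combine_profiles(profiles: list[SizeProfile], smoothing: float | None = None) -> SizeProfile:
    """Pool per-sample (position, size) pairs into one dataset-level profile.

    Window sizes are computed per sample, but windows must be shared by
    the whole dataset for counts to be comparable, so the spline is
    refitted to the pooled pairs.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    chroms = {p.chrom for p in profiles}
    if len(chroms) > 1:
        raise ValueError(f"profiles span multiple chromosomes: {sorted(chroms)}")
    anchors = np.concatenate([p.anchors for p in profiles])
    sizes = np.concatenate([p.sizes for p in profiles])
    min_size = min(p.min_size for p in profiles)
    return SizeProfile(profiles[0].chrom, anchors, sizes, smoothing=smoothing,
                       min_size=min_size)


def _chain(profile: SizeProfile, start: int, stop: int, direction: int):
    """Midpoint-chained windows from ``start`` toward ``stop``.

    direction +1: windows [s, s+size), next s = (s + e) // 2.
    direction -1: windows [e-size, e), next e = (s + e) // 2.
    The final window is truncated at ``stop``.
    """
    out = []
    edge = start
    while True:
        size = max(2, int(round(profile(edge))))
        if direction > 0:
            s, e = edge, edge + size
            if e >= stop:
                if stop > s:
                    out.append((s, stop))
                break
            out.append((s, e))
            edge = (s + e) // 2
        else:
            s, e = edge - size, edge
            if s <= stop:
                if e > stop:
                    out.append((stop, e))
                break
            out.append((s, e))
            edge = (s + e) // 2
        if len(out) > 10_000_000:
            raise RuntimeError("window chain did not terminate")
    return out


def build_cis_windows(bait_pos: int, span: tuple[int, int], profile: SizeProfile,
                      chrom: str | None = None, mode: str = "nearbait",
                      k: int | None = None) -> WindowSet:
    """Two overlapping window chains growing left and right from the bait.

    ``span`` is the analysed region: the near-bait span (10 Mb for 6bp
    cutters, 2 Mb for 4bp, clipped at chromosome edges) or the whole
    chromosome.  Each window's size is the profile evaluated at its
    growing edge; adjacent windows start at the midpoint of their
    predecessor.
    """
    lo, hi = span
    if not (lo <= bait_pos <= hi):
        raise ValueError(f"bait {bait_pos} outside span {span}")
    chrom = chrom or profile.chrom

    right = _chain(profile, bait_pos, hi, +1)
    left = _chain(profile, bait_pos, lo, -1)
    if not left:
        warnings.warn("bait at span edge: left chain empty", stacklevel=2)
    if not right:
        warnings.warn("bait at span edge: right chain empty", stacklevel=2)

    wins = []
    for i, (s, e) in enumerate(reversed(left)):
        wins.append(Window(chrom, s, e, i, "left"))
    for j, (s, e) in enumerate(right):
        wins.append(Window(chrom, s, e, len(left) + j, "right"))
    return WindowSet(chrom, wins, mode, k or DEFAULT_K.get(mode, 5), bait_pos=bait_pos)


def build_trans_windows(chrom_len: int, profile: SizeProfile,
                        chrom: str | None = None, k: int | None = None) -> WindowSet:
    """Single left-to-right overlapping chain covering a trans chromosome."""
    chrom = chrom or profile.chrom
    chain = _chain(profile, 0, chrom_len, +1)
    wins = [Window(chrom, s, e, i, "trans") for i, (s, e) in enumerate(chain)]
    return WindowSet(chrom, wins, "trans", k or DEFAULT_K["trans_6bp"])
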