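"""Window counts, normalization and the HMM observation matrix.

Three steps turn per-fragment read counts into model observations:

1. PCR-artifact trimming: within each window, fragment counts above the
   75th quantile of the window's observed-fragment counts are capped at
   that quantile, damping isolated spikes unsupported by neighbours.
2. Median-of-ratios size factors across samples, treating each window
   as a feature, so replicate depths are comparable.
3. log10(normalized count + 1) per window and, for cis analyses,
   the covariate log10(bait distance + 1): on this scale the decay of
   contact counts with genomic distance is approximately linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fourc.fragmap import FragmentCounts
from fourc.windows import WindowSet

TRIM_QUANTILE = 0.75


@dataclass
class WindowCountMatrix:
    """Per-window counts across samples, plus bait distances in cis.

    ``raw`` holds untrimmed window sums (used for differential testing),
    ``trimmed`` the PCR-capped sums that feed normalization and the HMM.
    """

    window_set: WindowSet
    sample_ids: list[str]
    raw: np.ndarray                      # (T, M) floats
    trimmed: np.ndarray                  # (T, M) floats
    distances: np.ndarray | None = None  # (T,) bp, cis only
    size_factors_: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.raw.shape[0]

    @property
    def n_samples(self) -> int:
        return self.raw.shape[1]

    def normalized(self, trimmed: bool = True) -> np.ndarray:
        f = self.size_factors_ if self.size_factors_ is not None else size_factors(self)
        return (self.trimmed if trimmed else self.raw) / f


@dataclass
class ObservationMatrix:
    """log10-scale inputs to the HMM."""

    x: np.ndarray                 # (T, M) log10(normalized count + 1)
    z: np.ndarray | None = None   # (T,) log10(distance + 1); None in trans

    def __post_init__(self) -> None:
        if not np.isfinite(self.x).all():
            raise ValueError("non-finite observations")
        if self.z is not None and len(self.z) != self.x.shape[0]:
            raise ValueError("covariate length mismatch")


def trim_window_counts(fragment_counts, quantile: float = TRIM_QUANTILE) -> float:
    """Cap a window's observed-fragment counts at their 75th quantile, then sum.

    The quantile is the linear-interpolation (R type-7) quantile over
    observed fragments only; an empty window totals zero.
    """
    c = np.asarray(fragment_counts, dtype=float)
    c = c[c >= 1]
    if len(c) == 0:
        return 0.0
    q = np.quantile(c, quantile)
    return float(np.minimum(c, q).sum())


def window_counts(
    samples: list[FragmentCounts],
    window_set: WindowSet,
    bait_pos: int | None = None,
    trim_quantile: float = TRIM_QUANTILE,
) -> WindowCountMatrix:
    """Aggregate per-fragment counts into window totals for every sample.

    A fragment belongs to a window when its midpoint falls inside the
    window interval; overlapping windows share fragments by design.
    """
    if not samples:
        raise ValueError("no samples")
    fmap = samples[0].fmap
    for s in samples[1:]:
        if s.fmap is not fmap and len(s.fmap) != len(fmap):
            raise ValueError("samples must share one fragment map")

    chrom = window_set.chrom
    frag_idx = [i for i, f in enumerate(fmap) if f.chrom == chrom]
    mids = np.array([fmap.fragments[i].mid for i in frag_idx])
    order = np.argsort(mids)
    mids = mids[order]
    frag_idx = np.asarray(frag_idx)[order]

    T, M = len(window_set), len(samples)
    raw = np.zeros((T, M))
    trimmed = np.zeros((T, M))
    per_sample = [s.counts[frag_idx] for s in samples]
    for t, w in enumerate(window_set):
        lo = np.searchsorted(mids, w.start, side="left")
        hi = np.searchsorted(mids, w.end, side="left")
        for m in range(M):
            c = per_sample[m][lo:hi]
            raw[t, m] = c.sum()
            trimmed[t, m] = trim_window_counts(c, trim_quantile)

    distances = None
    bait = bait_pos if bait_pos is not None else window_set.bait_pos
    if window_set.mode in ("nearbait", "cis"):
        if bait is None:
            raise ValueError("bait position required for cis windows")
        distances = np.array([abs(w.mid - bait) for w in window_set])
    return WindowCountMatrix(window_set, [s.sample_id for s in samples],
                             raw, trimmed, distances)


def size_factors(matrix: WindowCountMatrix | np.ndarray, trimmed: bool = True) -> np.ndarray:
    """Median-of-ratios size factors, each window treated as a feature.

    factor_m = median over windows (positive in every sample) of
    count_{t,m} / geometric-mean_t.
    """
    counts = matrix if isinstance(matrix, np.ndarray) else (
        matrix.trimmed if trimmed else matrix.raw
    )
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a (windows x samples) matrix with >= 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no window has positive counts in every sample; use larger windows"
        )
    sub = counts[positive]
    geomean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    if isinstance(matrix, WindowCountMatrix):
        matrix.size_factors_ = factors
    return factors


def make_observations(matrix: WindowCountMatrix, mode: str | None = None) -> ObservationMatrix:
    """log10(normalized + 1) observations and the cis distance covariate."""
    mode = mode or matrix.window_set.mode
    norm = matrix.normalized(trimmed=True)
    assert (norm >= 0).all()
    x = np.log10(norm + 1.0)
    z = None
    if mode in ("nearbait", "cis"):
        if matrix.distances is None:
            raise ValueError("cis observations need bait distances")
        z = np.log10(matrix.distances + 1.0)
    return ObservationMatrix(x, z)
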