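"""Replicate similarity, differential interactions and peak enrichment.

Downstream of domain calling, three questions arise: how reproducible
are the HI domains across biological replicates, do two conditions with
the same bait interact quantitatively differently, and are called
domains enriched for an external feature such as accessible chromatin?
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fourc import intervals
from fourc.normalize import size_factors


# --------------------------------------------------------------------------- #
# similarity index
# --------------------------------------------------------------------------- #

@dataclass
class SimilarityResult:
    cs: float            # raw inclusion-exclusion score, in [0, m]
    normalized: float    # cs / m, in [0, 1]
    m: int
    overlap_frac: float
    retained: list[list[tuple[int, int]]]


def similarity_index(domain_sets, overlap_frac: float = 0.5) -> SimilarityResult:
    """Inclusion-exclusion overlap score across m replicates' HI domains.

    A domain is first retained only if at least ``overlap_frac`` of its
    length is covered by the union of the other replicates' domains.
    With a_S the base pairs covered by the intersection of subset S of
    the retained sets and U the base pairs of their union,

        CS_m = m/(m-1) * (sum_{|S|=2} a_S - sum_{|S|=3} a_S + ...) / U

    which is m for identical replicates; dividing by m normalizes to
    [0, 1] for comparisons across replicate counts.
    """
    sets = [intervals.merge(s) for s in domain_sets]
    m = len(sets)
    if m < 2:
        raise ValueError("similarity index needs at least 2 replicates")
    if any(len(s) == 0 for s in sets):
        warnings.warn("a replicate has no domains; similarity is 0", stacklevel=2)
        return SimilarityResult(0.0, 0.0, m, overlap_frac, [[] for _ in sets])

    retained = []
    for i, s in enumerate(sets):
        others = intervals.merge(
            [iv for j, t in enumerate(sets) if j != i for iv in t]
        )
        keep = [
            (a, b) for a, b in s
            if intervals.overlap_bp([(a, b)], others) >= overlap_frac * (b - a)
        ]
        retained.append(keep)

    union = intervals.merge([iv for s in retained for iv in s])
    denom = intervals.total_bp(union)
    if denom == 0:
        return SimilarityResult(0.0, 0.0, m, overlap_frac, retained)

    # inclusion-exclusion: + pairs, - triples, + quadruples, ...
    signed = 0.0
    for r in range(2, m + 1):
        sign = 1.0 if r % 2 == 0 else -1.0
        for subset in itertools.combinations(range(m), r):
            signed += sign * intervals.total_bp(
                intervals.intersect_many([retained[i] for i in subset])
            )
    cs = (m / (m - 1)) * signed / denom
    return SimilarityResult(cs, cs / m, m, overlap_frac, retained)


# --------------------------------------------------------------------------- #
# dataset-specific interacting domains and differential testing
# --------------------------------------------------------------------------- #

@dataclass
class DidSet:
    """Union-merge of HI domains over conditions: the testing universe."""

    chrom: str
    dids: list[tuple[int, int]]
    sources: list[list[str]]     # condition labels contributing to each DID

    def __len__(self) -> int:
        return len(self.dids)


def build_dids(domain_sets: dict[str, list[tuple[int, int]]], chrom: str = "chr") -> DidSet:
    """Merge per-condition consensus domains into DIDs with provenance."""
    nonempty = {c: intervals.merge(d) for c, d in domain_sets.items()}
    if len(nonempty) < 2:
        raise ValueError("DIDs need at least 2 conditions")
    if all(len(d) == 0 for d in nonempty.values()):
        raise ValueError("no domains in any condition")
    dids = intervals.merge([iv for d in nonempty.values() for iv in d])
    sources = [
        sorted(c for c, d in nonempty.items() if intervals.overlap_bp([iv], d) > 0)
        for iv in dids
    ]
    return DidSet(chrom, dids, sources)


@dataclass
class DifferentialResult:
    """Per-window negative-binomial Wald test between two conditions."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    log2_fold_change: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray
    significant: np.ndarray      # padj < fdr
    fdr: float = 0.05


def nb_differential(
    counts: np.ndarray,
    condition: np.ndarray,
    fdr: float = 0.05,
    allow_single_replicate: bool = False,
) -> DifferentialResult:
    """Test each window for a condition effect under a negative-binomial model.

    ``counts`` is a raw (windows x samples) matrix of window counts
    restricted to DIDs; ``condition`` labels each column (two levels).
    Counts are size-factor normalized, and the NB dispersion of each
    window is estimated by method of moments pooled across both
    conditions.  With the 2-3 replicates typical of 4C a per-window
    moment estimate is far too noisy to power a test, so, in the spirit
    of the shrinkage used by dedicated count-model packages, each
    window's dispersion is floored at the across-window mean estimate.
    A Wald test on the log mean ratio against a standard normal yields
    p-values that are Benjamini-Hochberg adjusted.
    """
    counts = np.asarray(counts, dtype=float)
    condition = np.asarray(condition)
    levels = sorted(set(condition.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly 2 conditions required, got {levels}")
    ia = np.where(condition == levels[0])[0]
    ib = np.where(condition == levels[1])[0]
    if (len(ia) < 2 or len(ib) < 2) and not allow_single_replicate:
        raise ValueError("each condition needs >= 2 replicates "
                         "(set allow_single_replicate to override)")

    factors = size_factors(counts)
    norm = counts / factors
    na, nb_ = len(ia), len(ib)
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    var_a = norm[:, ia].var(axis=1, ddof=1) if na > 1 else np.zeros(len(norm))
    var_b = norm[:, ib].var(axis=1, ddof=1) if nb_ > 1 else np.zeros(len(norm))

    # method-of-moments NB dispersion, pooled across conditions:
    # var = mu + alpha * mu^2  =>  alpha = (var - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(mean_a > 0, (var_a - mean_a) / mean_a ** 2, 0.0)
        alpha_b = np.where(mean_b > 0, (var_b - mean_b) / mean_b ** 2, 0.0)
    weights = np.array([max(na - 1, 0), max(nb_ - 1, 0)], dtype=float)
    if weights.sum() > 0:
        alpha = (alpha_a * weights[0] + alpha_b * weights[1]) / weights.sum()
    else:   # single replicate per condition: no within-condition variance
        alpha = np.zeros(len(mean_a))
    alpha = np.maximum(alpha, 0.0)
    # dispersion sharing across windows: floor each window's noisy moment
    # estimate at the across-window mean
    alpha = np.maximum(alpha, alpha.mean())
    alpha = np.maximum(alpha, 1e-8)

    pseudo = 0.5
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    # delta-method variance of log(mean) under NB: (1/mu + alpha) / n
    se2 = (1.0 / np.maximum(mean_a, pseudo) + alpha) / na \
        + (1.0 / np.maximum(mean_b, pseudo) + alpha) / nb_
    wald = (np.log(mean_b + pseudo) - np.log(mean_a + pseudo)) / np.sqrt(se2)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    _, padj, _, _ = multipletests(pvalue, method="fdr_bh")
    return DifferentialResult(mean_a, mean_b, log2fc, pvalue, padj,
                              padj < fdr, fdr)


# --------------------------------------------------------------------------- #
# peak enrichment against a repositioning null
# --------------------------------------------------------------------------- #

@dataclass
class EnrichmentResult:
    observed_bp: int
    null_mean: float
    null_sd: float
    ratio: float
    n_repositionings: int
    seed: int


def peak_enrichment(
    domains,
    peaks,
    chrom_len: int,
    R: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Ratio of peak coverage inside domains to a repositioning null.

    Each null draw repositions every domain uniformly along the
    chromosome, size-preserving and without overlaps (rejection
    sampling), and measures peak base pairs inside the repositioned
    domains.  The observed/mean(null) ratio is ~1 when domains sit on
    peaks no more than chance expects.
    """
    domains = intervals.merge(domains)
    peaks = intervals.merge(peaks)
    if R < 1:
        raise ValueError("R must be >= 1")
    for s, e in domains:
        if e - s > chrom_len:
            raise ValueError("domain longer than the chromosome")
    observed = intervals.overlap_bp(domains, peaks)
    if not domains:
        return EnrichmentResult(0, 0.0, 0.0, 0.0, R, seed)

    rng = np.random.default_rng(seed)
    lengths = [e - s for s, e in domains]
    nulls = np.empty(R)
    for r in range(R):
        placed: list[tuple[int, int]] = []
        for L in lengths:
            for _ in range(1000):
                s = int(rng.integers(0, chrom_len - L + 1))
                iv = (s, s + L)
                if all(iv[1] <= p[0] or iv[0] >= p[1] for p in placed):
                    placed.append(iv)
                    break
            else:
                raise RuntimeError("could not place domains without overlap; "
                                   "domains cover too much of the chromosome")
        nulls[r] = intervals.overlap_bp(placed, peaks)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std())
    ratio = observed / null_mean if null_mean > 0 else 0.0
    if observed == 0:
        ratio = 0.0
    return EnrichmentResult(int(observed), null_mean, null_sd, float(ratio), R, seed)
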