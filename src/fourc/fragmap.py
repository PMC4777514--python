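"""Reduced-genome construction and per-fragment read counts.

A 4C-Seq read is sequenced outward from the bait primer and, after
trimming, consists of the captured fragment sequence directly adjacent
to a primary restriction site.  Instead of aligning against the whole
genome, reads are assigned to a *reduced genome*: the set of flanking
sequences of a fixed read length on either side of every restriction
site ("potential fragments").  A potential fragment with at least one
read is an "observed fragment".

Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np


# --------------------------------------------------------------------------- #
# types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RestrictionSite:
    """A forward-strand occurrence of the enzyme's recognition motif."""

    chrom: str
    pos: int          # 0-based offset of the motif start
    motif: str


@dataclass(frozen=True)
class PotentialFragment:
    """Flanking sequence adjacent to a restriction site.

    ``side`` is 'up' for the flank ending at the motif start and 'down'
    for the flank starting just after the motif.  ``unique`` is True when
    ``seq`` occurs exactly once genome-wide at the configured read
    length; only unique fragments receive read counts.  ``truncated``
    marks flanks clipped at a chromosome edge.
    """

    chrom: str
    start: int
    end: int
    side: str
    seq: str
    unique: bool
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment interval [{self.start}, {self.end})")

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


class FragmentMap:
    """Ordered collection of potential fragments, indexed per chromosome."""

    def __init__(self, fragments: list[PotentialFragment]):
        self.fragments = sorted(fragments, key=lambda f: (f.chrom, f.start, f.side))
        seen = set()
        for f in self.fragments:
            key = (f.chrom, f.start, f.side)
            if key in seen:
                raise ValueError(f"duplicate fragment {key}")
            seen.add(key)
        self._by_chrom: dict[str, list[PotentialFragment]] = {}
        for f in self.fragments:
            self._by_chrom.setdefault(f.chrom, []).append(f)
        self._index = {(f.chrom, f.start, f.end): i for i, f in enumerate(self.fragments)}

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def chrom_fragments(self, chrom: str) -> list[PotentialFragment]:
        return self._by_chrom.get(chrom, [])

    def locate(self, chrom: str, start: int, end: int) -> int | None:
        """Row index of the fragment with exactly these coordinates."""
        return self._index.get((chrom, start, end))

    def containing(self, chrom: str, pos: int) -> int | None:
        """Row index of a fragment whose interval contains ``pos`` (nearest on tie)."""
        best = None
        for f in self.chrom_fragments(chrom):
            if f.start <= pos < f.end:
                i = self._index[(f.chrom, f.start, f.end)]
                if best is None or abs(f.mid - pos) < abs(self.fragments[best].mid - pos):
                    best = i
        return best

    def nearest(self, chrom: str, pos: int, max_dist: int | None = None) -> int | None:
        """Row index of the fragment whose midpoint is closest to ``pos``.

        The bait coordinate usually points at a restriction site, which sits
        in the gap between two flanks, so exact containment can fail.
        """
        best, best_d = None, None
        for f in self.chrom_fragments(chrom):
            d = abs(f.mid - pos)
            if best_d is None or d < best_d:
                best, best_d = self._index[(f.chrom, f.start, f.end)], d
        if best is None or (max_dist is not None and best_d > max_dist):
            return None
        return best

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                name = f"{f.side}:{'u' if f.unique else 'm'}{':t' if f.truncated else ''}"
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\n")


@dataclass
class FragmentCounts:
    """Read counts aligned to the fragment order of a :class:`FragmentMap`."""

    sample_id: str
    fmap: FragmentMap
    counts: np.ndarray                  # shape (len(fmap),), non-negative
    bait: tuple[str, int] | None = None
    enzyme_class: str | None = None     # '4bp' | '6bp'

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.fmap),):
            raise ValueError("counts length must equal the fragment map size")
        if (self.counts < 0).any():
            raise ValueError("negative read count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def observed_mask(self) -> np.ndarray:
        return self.counts >= 1


@dataclass(frozen=True)
class QcReport:
    """Standard 4C-Seq dataset quality metrics.

    A sample passes when it retains at least one million reads, places at
    least 40% of them on the bait chromosome, and at least 40% of the
    potential fragments in the near-bait span (2 Mb for 6bp cutters,
    200 kb for 4bp cutters) are observed.
    """

    total_reads: int
    cis_fraction: float
    nearbait_coverage: float
    pass_: bool

    MIN_READS = 1_000_000
    MIN_CIS_FRACTION = 0.40
    MIN_NEARBAIT_COVERAGE = 0.40


NEARBAIT_QC_SPAN = {"6bp": 2_000_000, "4bp": 200_000}


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def digest_genome(seqs: dict[str, str], motif: str) -> list[RestrictionSite]:
    """Find every forward-strand occurrence of ``motif`` in each chromosome.

    Overlapping occurrences are all reported.  Soft-masked (lowercase)
    sequence is uppercased first.  Most 4C restriction enzymes recognise
    palindromic sites, for which a forward-strand scan is complete; a
    non-palindromic motif triggers a warning.
    """
    motif = motif.upper()
    if not motif or any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be non-empty ACGT, got {motif!r}")
    if motif != _revcomp(motif):
        warnings.warn(
            f"motif {motif} is not palindromic; only forward-strand sites are reported",
            stacklevel=2,
        )
    sites = []
    for chrom in sorted(seqs):
        seq = seqs[chrom].upper()
        i = seq.find(motif)
        while i != -1:
            sites.append(RestrictionSite(chrom, i, motif))
            i = seq.find(motif, i + 1)   # step 1 so overlapping hits are kept
    return sites


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def build_reduced_genome(
    seqs: dict[str, str], sites: list[RestrictionSite], read_len: int
) -> FragmentMap:
    """Build the reduced genome: read-length flanks on both sides of every site.

    Uniqueness is exact-sequence uniqueness at ``read_len`` over the
    forward strand of the whole genome (overlapping occurrences counted).
    Non-unique and edge-truncated flanks are retained but flagged.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    upper = {c: s.upper() for c, s in seqs.items()}

    raw: list[tuple[str, int, int, str, str, bool]] = []
    for site in sites:
        seq = upper[site.chrom]
        m = len(site.motif)
        # upstream flank ends at the motif start
        up_start, up_end = max(0, site.pos - read_len), site.pos
        if up_end > up_start:
            raw.append((site.chrom, up_start, up_end, "up",
                        seq[up_start:up_end], up_end - up_start < read_len))
        # downstream flank starts just after the motif
        dn_start, dn_end = site.pos + m, min(len(seq), site.pos + m + read_len)
        if dn_end > dn_start:
            raw.append((site.chrom, dn_start, dn_end, "down",
                        seq[dn_start:dn_end], dn_end - dn_start < read_len))

    flank_set = {r[4] for r in raw if len(r[4]) == read_len}
    occ = _genome_occurrences(upper, flank_set, read_len)

    frags = []
    seen = set()
    for chrom, start, end, side, fseq, truncated in raw:
        if (chrom, start, side) in seen:    # adjacent identical motifs can collide
            continue
        seen.add((chrom, start, side))
        unique = (not truncated) and occ[fseq] == 1
        frags.append(PotentialFragment(chrom, start, end, side, fseq, unique, truncated))
    return FragmentMap(frags)


def _roll_hashes(codes: np.ndarray, L: int) -> np.ndarray:
    """64-bit wraparound polynomial hashes of every length-L window."""
    B = np.uint64(1000003)
    n = len(codes) - L + 1
    acc = np.zeros(n, dtype=np.uint64)
    for j in range(L):
        acc = acc * B + codes[j : j + n]
    return acc


def _genome_occurrences(
    upper: dict[str, str], targets: set[str], L: int
) -> Counter[str]:
    """Exact genome-wide occurrence counts of the target sequences.

    A rolling hash gives candidate counts in one vectorized pass; a hash
    count of 1 is provably exact (collisions only inflate), and the rare
    candidates with count > 1 are re-counted by explicit substring search.
    """
    occ: Counter[str] = Counter()
    if not targets:
        return occ
    hash_counts: Counter[int] = Counter()
    for seq in upper.values():
        if len(seq) < L:
            continue
        codes = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.uint64)
        h, cnt = np.unique(_roll_hashes(codes, L), return_counts=True)
        for hv, c in zip(h.tolist(), cnt.tolist()):
            hash_counts[hv] += c
    for t in targets:
        tcodes = np.frombuffer(t.encode(), dtype=np.uint8).astype(np.uint64)
        th = int(_roll_hashes(tcodes, L)[0])
        c = hash_counts.get(th, 0)
        if c > 1:   # could include collisions: verify exactly
            c = 0
            for seq in upper.values():
                i = seq.find(t)
                while i != -1:
                    c += 1
                    i = seq.find(t, i + 1)
        occ[t] = c
    return occ


def assign_reads(
    reads: list[str],
    fmap: FragmentMap,
    sample_id: str = "sample",
    bait: tuple[str, int] | None = None,
    enzyme_class: str | None = None,
) -> FragmentCounts:
    """Assign trimmed reads to unique fragments by exact sequence match.

    A read increments exactly one fragment when it equals the sequence of
    a unique fragment; reads matching non-unique fragments or nothing are
    discarded.  This is a desk-scale, zero-mismatch stand-in for a real
    aligner and is intended for simulated data.
    """
    lookup: dict[str, int] = {}
    for i, f in enumerate(fmap):
        if f.unique:
            lookup[f.seq] = i
    counts = np.zeros(len(fmap), dtype=np.int64)
    for read in reads:
        i = lookup.get(read.upper())
        if i is not None:
            counts[i] += 1
    return FragmentCounts(sample_id, fmap, counts, bait=bait, enzyme_class=enzyme_class)


def write_bedgraph(counts: FragmentCounts, path, observed_only: bool = True) -> None:
    """Write per-fragment counts as a 4-column bedGraph."""
    with open(path, "w") as fh:
        for f, c in zip(counts.fmap, counts.counts):
            if observed_only and c < 1:
                continue
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{c:g}\n")


def read_bedgraph(
    path,
    fmap: FragmentMap,
    sample_id: str | None = None,
    bait: tuple[str, int] | None = None,
    enzyme_class: str | None = None,
) -> FragmentCounts:
    """Read a 4-column bedGraph of per-fragment counts.

    Every record must correspond exactly to a fragment of ``fmap``;
    track/browser lines and comments are skipped.  Errors name the
    offending line number.
    """
    counts = np.zeros(len(fmap), dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            idx = fmap.locate(chrom, start, end)
            if idx is None:
                raise ValueError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} is not a "
                    "fragment of the reduced genome"
                )
            counts[idx] += value
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    name = sample_id if sample_id is not None else str(path)
    return FragmentCounts(name, fmap, counts, bait=bait, enzyme_class=enzyme_class)


def remove_bait_artifacts(
    counts: FragmentCounts, bait: tuple[str, int] | None = None, radius: int = 1
) -> FragmentCounts:
    """Zero out self-ligation and non-digestion signal around the bait.

    The bait fragment and all flanks of restriction sites within
    ``radius`` sites of it are set to zero; these carry the undigested
    and self-ligated circles rather than genuine contacts.  The removed
    read mass is recorded on the returned object as ``removed_mass``.
    """
    bait = bait or counts.bait
    if bait is None:
        raise ValueError("bait position required")
    chrom, pos = bait
    bait_idx = counts.fmap.containing(chrom, pos)
    if bait_idx is None:
        bait_idx = counts.fmap.nearest(chrom, pos, max_dist=1000)
    if bait_idx is None:
        raise ValueError(f"bait {chrom}:{pos} does not resolve to any fragment")

    chrom_frags = counts.fmap.chrom_fragments(chrom)
    bait_frag = counts.fmap.fragments[bait_idx]
    # order of this fragment among the chromosome's fragments
    j = next(i for i, f in enumerate(chrom_frags) if f.start == bait_frag.start and f.side == bait_frag.side)
    # each site contributes up to two flanks; masking 'radius' sites on each
    # side corresponds to 2*radius flanking fragments on each side
    lo, hi = max(0, j - 2 * radius), min(len(chrom_frags), j + 2 * radius + 1)
    masked = chrom_frags[lo:hi]

    new = counts.counts.copy()
    removed = 0
    for f in masked:
        i = counts.fmap.locate(f.chrom, f.start, f.end)
        removed += new[i]
        new[i] = 0
    out = replace(counts, counts=new)
    out.removed_mass = int(removed)
    return out


def qc(counts: FragmentCounts, fmap: FragmentMap | None = None) -> QcReport:
    """Compute standard 4C-Seq quality metrics for one sample."""
    fmap = fmap or counts.fmap
    if counts.bait is None or counts.enzyme_class is None:
        raise ValueError("bait and enzyme_class must be set for QC")
    chrom, pos = counts.bait
    span = NEARBAIT_QC_SPAN[counts.enzyme_class]

    total = counts.total
    if total == 0:
        return QcReport(0, 0.0, 0.0, False)

    cis = sum(
        c for f, c in zip(fmap, counts.counts) if f.chrom == chrom
    )
    cis_fraction = cis / total

    lo, hi = pos - span // 2, pos + span // 2
    in_span = [
        (f, c) for f, c in zip(fmap, counts.counts)
        if f.chrom == chrom and lo <= f.mid < hi
    ]
    if in_span:
        coverage = sum(1 for _, c in in_span if c >= 1) / len(in_span)
    else:
        coverage = 0.0

    pass_ = (
        total >= QcReport.MIN_READS
        and cis_fraction >= QcReport.MIN_CIS_FRACTION
        and coverage >= QcReport.MIN_NEARBAIT_COVERAGE
    )
    return QcReport(total, cis_fraction, coverage, pass_)
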