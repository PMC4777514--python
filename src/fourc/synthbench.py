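"""Synthetic 4C-Seq datasets with known ground truth.

The generator produces a random genome, digests it in silico, and draws
per-fragment read counts whose log10 means follow the same
linear-distance-decay structure the cis HMM assumes, with
negative-binomial count noise (the marginal distribution that also
underlies the differential test) and optional PCR spikes.  True HI/LI
domain intervals are recorded so that every downstream stage — window
building, normalization, HMM training, domain calling, similarity and
differential testing — can be benchmarked against base-pair truth
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fourc import compare, fragmap, hmm, intervals, normalize, windows
from fourc.fragmap import FragmentCounts, FragmentMap


@dataclass
class SimulationSpec:
    """Ground-truth description of one simulated 4C experiment.

    Defaults describe a desk-scale 4bp-cutter experiment: a 2 Mb cis
    chromosome (the near-bait span of a 4bp cutter), GATC sites at their
    natural ~256 bp random-sequence spacing, the bait at the centre, two
    HI domains and two LI domains, and per-state log10 count decay
    parameters that satisfy the HMM consistency constraints so the truth
    is recoverable in principle.
    """

    chrom: str = "chrS"
    chrom_len: int = 2_000_000
    motif: str = "GATC"
    enzyme_class: str = "4bp"
    read_len: int = 20
    bait_pos: int | None = None          # default: chromosome centre
    hi_domains: list[tuple[int, int]] = field(
        default_factory=lambda: [(400_000, 500_000), (1_350_000, 1_450_000)]
    )
    li_domains: list[tuple[int, int]] = field(
        default_factory=lambda: [(250_000, 330_000), (1_550_000, 1_650_000)]
    )
    # per-state emission structure on the log10(count+1) scale per fragment
    beta0: tuple[float, float, float] = (0.9, 1.45, 2.1)
    beta1: tuple[float, float, float] = (-0.14, -0.14, -0.14)
    sigma: tuple[float, float, float] = (0.22, 0.22, 0.22)
    m_replicates: int = 2
    nb_dispersion: float = 0.05
    spike_rate: float = 0.0              # fraction of fragments hit by PCR spikes
    spike_factor: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bait_pos is None:
            self.bait_pos = self.chrom_len // 2
        merged = intervals.merge(self.hi_domains + self.li_domains)
        if intervals.total_bp(merged) != sum(
            e - s for s, e in self.hi_domains + self.li_domains
        ):
            raise ValueError("true domains must not overlap")
        b0 = np.asarray(self.beta0)
        if (np.diff(b0) < hmm.EPS_BETA).any() or (np.asarray(self.beta1) >= 0).any():
            raise ValueError("emission parameters must satisfy the HMM constraints")


def simulate_genome(spec: SimulationSpec, rng=None) -> tuple[dict[str, str], FragmentMap]:
    """Random genome plus its reduced genome for the configured enzyme.

    Uniform random sequence gives the motif its natural expected spacing
    of 4^len(motif) bp, matching real-genome densities of 4bp vs 6bp
    cutters.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if 4 ** len(spec.motif) > spec.chrom_len:
        raise ValueError("chromosome too short for the motif's natural spacing")
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = alphabet[rng.integers(0, 4, size=spec.chrom_len)].tobytes().decode()
    seqs = {spec.chrom: seq}
    sites = fragmap.digest_genome(seqs, spec.motif)
    fmap = fragmap.build_reduced_genome(seqs, sites, spec.read_len)
    return seqs, fmap


def _true_state(mid: float, spec: SimulationSpec) -> int:
    for s, e in spec.hi_domains:
        if s <= mid < e:
            return 3
    for s, e in spec.li_domains:
        if s <= mid < e:
            return 2
    return 1


def simulate_counts(
    spec: SimulationSpec, fmap: FragmentMap, rng=None, depth_scale: float = 1.0
) -> tuple[list[FragmentCounts], list[tuple[int, int]]]:
    """Draw per-replicate fragment counts from the ground-truth model.

    Per fragment the expected log10 count is beta0_state + beta1_state *
    log10(distance+1) plus Gaussian state noise; the count is NB with
    that back-transformed mean and the configured dispersion.  Replicates are
    i.i.d. given the truth.  Returns the replicates and the true HI
    intervals.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    mids = np.array([f.mid for f in fmap])
    states = np.array([_true_state(m, spec) for m in mids])
    logd = np.log10(np.abs(mids - spec.bait_pos) + 1.0)
    b0 = np.asarray(spec.beta0)[states - 1]
    b1 = np.asarray(spec.beta1)[states - 1]
    sg = np.asarray(spec.sigma)[states - 1]

    replicates = []
    for m in range(spec.m_replicates):
        log_mu = b0 + b1 * logd + rng.normal(0.0, sg)
        mu = np.maximum(depth_scale * (10.0 ** log_mu - 1.0), 1e-6)
        if spec.nb_dispersion > 0:
            # NB with var = mu + alpha mu^2, via gamma-Poisson mixture
            shape = 1.0 / spec.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        if spec.spike_rate > 0:
            spiked = rng.random(len(counts)) < spec.spike_rate
            counts = np.where(spiked, np.round(counts * spec.spike_factor), counts)
        counts = np.where([f.unique for f in fmap], counts, 0)
        replicates.append(FragmentCounts(
            f"rep{m + 1}", fmap, counts.astype(np.int64),
            bait=(spec.chrom, spec.bait_pos), enzyme_class=spec.enzyme_class,
        ))
    return replicates, intervals.merge(spec.hi_domains)


def write_truth_bed(truth, chrom: str, path) -> None:
    with open(path, "w") as fh:
        for s, e in truth:
            fh.write(f"{chrom}\t{s}\t{e}\ttrue_HI\n")


@dataclass
class RecoveryReport:
    precision: float          # bp of called consensus inside truth / called bp
    recall: float             # bp of truth recovered / truth bp
    similarity: float         # replicate similarity index (normalized)
    called: list[tuple[int, int]]
    truth: list[tuple[int, int]]
    model: hmm.CisModel


def end_to_end_recovery(spec: SimulationSpec, seed: int | None = None,
                        k: int | None = None) -> RecoveryReport:
    """Run the full pipeline on simulated data and score domain recovery.

    Simulate genome and counts, mask the bait, build the dataset-level
    adaptive windows, normalize, bootstrap-train the cis HMM, decode each
    replicate, call consensus domains, and compare them base-pair-wise
    against the true HI intervals.
    """
    if spec.m_replicates < 2:
        raise ValueError("recovery benchmark needs >= 2 replicates")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    _, fmap = simulate_genome(spec, rng=rng)
    replicates, truth = simulate_counts(spec, fmap, rng=rng)
    replicates = [fragmap.remove_bait_artifacts(r) for r in replicates]

    k = k if k is not None else windows.DEFAULT_K["nearbait"]
    profiles = []
    for rep in replicates:
        mask = rep.observed_mask()
        pos = np.array([f.mid for f, o in zip(fmap, mask) if o and f.chrom == spec.chrom])
        profiles.append(windows.fit_size_profile(pos, windows.knn_sizes(pos, k),
                                                 chrom=spec.chrom))
    profile = windows.combine_profiles(profiles)
    ws = windows.build_cis_windows(spec.bait_pos, (0, spec.chrom_len), profile,
                                   chrom=spec.chrom, mode="nearbait", k=k)

    matrix = normalize.window_counts(replicates, ws, bait_pos=spec.bait_pos)
    normalize.size_factors(matrix)
    obs = normalize.make_observations(matrix)

    train = hmm.bootstrap_training_sample(replicates, ws, "nearbait",
                                          seed=seed + 7, bait_pos=spec.bait_pos)
    model0 = hmm.init_params_cis(train[0])
    model = hmm.fit(model0, train)

    paths = hmm.viterbi(model, obs)
    domains = hmm.call_domains(
        {rep.sample_id: p for rep, p in zip(replicates, paths)}, ws
    )
    sim = (compare.similarity_index(list(domains.replicate_domains.values()))
           if all(domains.replicate_domains.values()) else None)

    called = domains.consensus
    called_bp = intervals.total_bp(called)
    truth_bp = intervals.total_bp(truth)
    hit = intervals.overlap_bp(called, truth)
    precision = hit / called_bp if called_bp else (1.0 if truth_bp == 0 else 0.0)
    recall = hit / truth_bp if truth_bp else 1.0
    return RecoveryReport(precision, recall,
                          sim.normalized if sim is not None else 0.0,
                          called, truth, model)
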