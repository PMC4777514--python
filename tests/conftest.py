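"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from fourc import fragmap, synthbench


@pytest.fixture(scope="session")
def toy_genome():
    """A 10 kb random genome with GATC sites, fixed seed."""
    rng = np.random.default_rng(42)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = alphabet[rng.integers(0, 4, size=10_000)].tobytes().decode()
    return {"chr1": seq}


@pytest.fixture(scope="session")
def toy_fmap(toy_genome):
    sites = fragmap.digest_genome(toy_genome, "GATC")
    return fragmap.build_reduced_genome(toy_genome, sites, read_len=12)


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled simulation: 400 kb chromosome, one HI and one LI domain."""
    return synthbench.SimulationSpec(
        chrom_len=400_000,
        bait_pos=200_000,
        hi_domains=[(80_000, 120_000)],
        li_domains=[(280_000, 320_000)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """Simulated fragment map + 2 replicates + truth for the small spec."""
    rng = np.random.default_rng(small_spec.seed)
    _, fmap = synthbench.simulate_genome(small_spec, rng=rng)
    reps, truth = synthbench.simulate_counts(small_spec, fmap, rng=rng)
    return fmap, reps, truth
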