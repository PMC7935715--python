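import pytest

from ffanips.cohort import SampleProfile, karyotype_to_copy_map, simulate_bin_counts
from ffanips.config import RunConfig
from ffanips.ff import normalize_depth
from ffanips.genome import build_genome


@pytest.fixture(scope="session")
def genome():
    """Default scaled genome (1/1000 GRCh38, 50 kb-equivalent bins)."""
    return build_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Coarser genome for fast unit tests (1/10000 scale, ~6k bins)."""
    return build_genome(scale=10_000, bin_width=50)


@pytest.fixture()
def config():
    return RunConfig()


def simulate_sample(genome, config, rng, ff=0.10, karyotype="euploid",
                    sex="XY", depth=500_000, sample_id="S0"):
    """One simulated sample's BinCounts."""
    profile = SampleProfile(sample_id, "B0", 25.0, ff, karyotype, sex)
    cmap = karyotype_to_copy_map(profile, genome)
    return simulate_bin_counts(profile, cmap, genome, depth, rng, config)


def simulate_ratios(genome, config, rng, **kwargs):
    """One simulated sample's normalized depth-ratio vector."""
    counts = simulate_sample(genome, config, rng, **kwargs)
    return normalize_depth(counts.total[:, 0], genome), counts.total[:, 0]
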