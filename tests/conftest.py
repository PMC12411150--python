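import numpy as np
import pytest

from aneuscan.genome import Chromosome, GenomeDefinition, make_bins
from aneuscan.normalize import NormalizedProfile


@pytest.fixture(scope="session")
def small_genome():
    """Two 40-Mb chromosomes, centromeres at 20 Mb: 200 bins each, arms of 100."""
    return GenomeDefinition(
        (
            Chromosome("chrA", 40_000_000, 20_000_000),
            Chromosome("chrB", 40_000_000, 20_000_000),
        )
    )


@pytest.fixture(scope="session")
def small_grid(small_genome):
    return make_bins(small_genome, 200_000)


@pytest.fixture(scope="session")
def one_chrom_grid():
    genome = GenomeDefinition((Chromosome("chr1", 40_000_000, 20_000_000),))
    return make_bins(genome, 200_000)


def profile_from_z(z, sample_id="s", usable=None):
    """Build a NormalizedProfile directly from a z vector (log2 ratio = z/5,
    an arbitrary smooth mapping adequate for segmentation-only tests)."""
    z = np.asarray(z, dtype=float)
    usable = np.ones(z.size, bool) if usable is None else np.asarray(usable, bool)
    return NormalizedProfile(
        sample_id=sample_id, z=z, log2_ratio=z / 5.0, usable_mask=usable
    )


def profile_from_log2(log2, sample_id="s", usable=None):
    log2 = np.asarray(log2, dtype=float)
    usable = np.ones(log2.size, bool) if usable is None else np.asarray(usable, bool)
    return NormalizedProfile(
        sample_id=sample_id, z=np.zeros_like(log2), log2_ratio=log2, usable_mask=usable
    )
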