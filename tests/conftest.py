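import numpy as np
import pytest

from haplonipt import simdata
from haplonipt.genetic_map import GeneticMap
from haplonipt.simdata import PathogenicSpec
from haplonipt.types import Diplotype, SNPMarker, SnpPanel


@pytest.fixture(scope="session")
def small_family():
    """A 120-SNP fully heterozygous family with one pathogenic variant per
    parent, shared across tests that only read it."""
    panel, mother, father = simdata.simulate_parental_diplotypes(
        n_snps=120,
        het_rate=1.0,
        pathogenic_spec={
            "mother": PathogenicSpec(4_975_000, hap=1),
            "father": PathogenicSpec(5_025_000, hap=2),
        },
        seed=11,
    )
    return panel, mother, father


@pytest.fixture(scope="session")
def uniform_map():
    return GeneticMap.uniform(4_000_000, 6_000_000, 1.0)


def tiny_panel(positions, chrom="chr1"):
    return SnpPanel([SNPMarker(chrom, int(p), "A", "G") for p in positions])


def diplotype(hap1, hap2, sample_id="s", **kw):
    return Diplotype(sample_id, np.array(hap1, np.int8), np.array(hap2, np.int8), **kw)
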