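import numpy as np
import pytest

from slafkit import sim
from slafkit.variants import MISSING, GenotypeMatrix, PopulationMap, VariantSite


def make_site(calls, chrom="Chr01", pos=100, ref="A", alt=("C",)):
    """Build a VariantSite from [(a, b), ...] allele-index pairs; None = missing."""
    gt = np.array(
        [(MISSING, MISSING) if c is None else c for c in calls], dtype=np.int16
    )
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=tuple(alt), genotypes=gt)


def make_matrix(columns, sample_ids=None, positions=None, chrom="Chr01", alleles=None):
    """Matrix from per-site call lists (columns[j] = calls of site j)."""
    n = len(columns[0])
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    sites = []
    for j, calls in enumerate(columns):
        ref, alt = alleles[j] if alleles else ("A", ("C",))
        pos = positions[j] if positions else 100 * (j + 1)
        sites.append(make_site(calls, chrom=chrom, pos=pos, ref=ref, alt=alt))
    return GenotypeMatrix(sample_ids, sites)


@pytest.fixture(scope="session")
def sim_dataset():
    """One structured simulation at the study's scale (213 samples, 5000 loci,
    K=3 ancestral pools at FST 0.1), shared read-only across tests."""
    config = sim.SimConfig(seed=1)
    matrix, truth = sim.simulate_population(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def truth_partition(sim_dataset):
    _, _, truth = sim_dataset
    return {
        sid: f"A{a}" for sid, a in zip(truth.sample_ids, truth.ancestral_assignment)
    }


@pytest.fixture()
def popmap(sim_dataset):
    _, _, truth = sim_dataset
    return PopulationMap(dict(zip(truth.sample_ids, truth.population_labels)))
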