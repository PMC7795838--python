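import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sagisou.datasets import GenotypeDataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(pop_calls: dict[str, list[list[list[int]]]],
                 loci: list[str] | None = None) -> GenotypeDataset:
    """Build a dataset from {pop: [[ [a1,a2] per locus ] per individual]}."""
    populations = list(pop_calls)
    individuals, pop_index, rows = [], [], []
    for p, (pop, inds) in enumerate(pop_calls.items()):
        for i, calls in enumerate(inds):
            individuals.append(f"{pop}_{i + 1:03d}")
            pop_index.append(p)
            rows.append(calls)
    n_loci = len(rows[0])
    return GenotypeDataset(
        populations=populations,
        pop_index=np.asarray(pop_index),
        individuals=individuals,
        loci=loci or [f"L{j + 1}" for j in range(n_loci)],
        calls=np.asarray(rows),
    )


@pytest.fixture
def disjoint_two_cluster() -> GenotypeDataset:
    """Two 2-individual clusters fixed for disjoint alleles at 6 loci."""
    a = [[100, 100]] * 6
    b = [[102, 102]] * 6
    return make_dataset({"North": [a, a], "South": [b, b]})


@pytest.fixture(scope="session")
def divergent_two_pop():
    """Two simulated populations with well-separated allele spectra."""
    from sagisou.synthetic import PopSimParams, simulate_genotypes

    params = PopSimParams(n_populations=2, n_individuals_per_pop=(20, 20),
                          n_loci=20, alleles_per_locus=4,
                          freq_concentration=0.2, seed=11)
    return simulate_genotypes(params)
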