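import numpy as np
import pytest

import matechoice as mc
from matechoice.genotype_io import GenotypeTable, Locus
from matechoice.synthetic_data import default_class_II


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated population with default (paper-like) noise rates."""
    return mc.simulate(mc.SimConfig(seed=11, n_territories=12, years=6))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free simulated population (mutation and typing error off)."""
    return mc.simulate(
        mc.SimConfig(seed=21, n_territories=20, years=8, mutation_rate=0.0,
                     genotyping_error=0.0)
    )


@pytest.fixture(scope="session")
def paper_scale_dataset():
    return mc.emulate_paper_scale(2016)


@pytest.fixture
def mhc2_locus():
    return default_class_II().to_locus()


def random_table(n_ind=20, n_loci=16, n_alleles=8, seed=0, missing_rate=0.0):
    """Random unstructured genotype table (microsatellites only)."""
    rng = np.random.default_rng(seed)
    loci = [Locus(f"L{j:02d}") for j in range(n_loci)]
    labels = [str(100 + 2 * a) for a in range(n_alleles)]
    calls = {}
    for i in range(n_ind):
        row = {}
        for locus in loci:
            if missing_rate and rng.random() < missing_rate:
                row[locus.name] = None
            else:
                a, b = rng.integers(0, n_alleles, 2)
                row[locus.name] = (labels[a], labels[b])
        calls[f"I{i:03d}"] = row
    return GenotypeTable(list(calls), loci, calls)
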