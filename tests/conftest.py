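import numpy as np
import pytest

from crfdrivers.catalog import Consequence, MutationCatalog, MutationRecord
from crfdrivers.simulate import SimulationConfig, generate_null_catalog


def make_record(sample="S1", gene="GENE", consequence=Consequence.MISSENSE,
                pos=None, fis=None):
    return MutationRecord(
        sample_id=sample, gene_id=gene, consequence=consequence,
        protein_pos=pos, fis=fis or {},
    )


@pytest.fixture
def toy_catalog():
    """Five genes, one scored missense PAM each: background pool
    {0.1, 0.2, 0.3, 0.4, 0.9} for FM oracle checks."""
    scores = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4, "E": 0.9}
    records = [
        make_record(sample=f"S{i+1}", gene=g, pos=10 + i, fis={"ma": s})
        for i, (g, s) in enumerate(sorted(scores.items()))
    ]
    return MutationCatalog(
        dataset_id="toy",
        site="toysite",
        samples=tuple(f"S{i+1}" for i in range(5)),
        records=records,
        protein_lengths={g: 100 for g in scores},
    )


@pytest.fixture(scope="session")
def small_null_catalog():
    """Mid-size passenger-only cohort shared by statistics tests."""
    config = SimulationConfig(n_samples=60, n_genes=120, mutations_per_sample=8.0, seed=11)
    return generate_null_catalog(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
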