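import numpy as np
import pandas as pd
import pytest

from vetkey import synthetic as syn
from vetkey.genotypes import GenotypeMatrix
from vetkey.morphology import load_trait_schema


@pytest.fixture(scope="session")
def schema():
    return load_trait_schema()


@pytest.fixture(scope="session")
def two_pop_config():
    """Two well-diverged populations plus F1s — the structure-recovery panel."""
    return syn.SimulationConfig(
        seed=11, n_snps=2000,
        pop_specs=[syn.PopSpec("A", 30, 0.5), syn.PopSpec("B", 30, 0.5)],
        hybrid_specs=[syn.HybridSpec("A", "B", "F1", 5, maternal_parent="B")],
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def two_pop_panel(two_pop_config):
    return syn.simulate_genotypes(two_pop_config)


@pytest.fixture(scope="session")
def default_panel():
    """Study-like panel (six clusters, hybrids, siblings) at one fixed seed."""
    cfg = syn.default_config(5)
    gm, roster, freqs = syn.simulate_genotypes(cfg)
    return cfg, gm, roster, freqs


def make_matrix(values, sample_ids=None, chrom_class="autosomal") -> GenotypeMatrix:
    values = np.asarray(values, dtype=float)
    n, j = values.shape
    return GenotypeMatrix(
        values=values,
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        snp_meta=pd.DataFrame({
            "locus": [f"L{k}" for k in range(j)],
            "position": list(range(j)),
            "chrom_class": chrom_class,
        }),
    )
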