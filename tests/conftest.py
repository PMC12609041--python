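import numpy as np
import pandas as pd
import pytest

from priorgs import TraitSpec, simulate_genotypes, simulate_phenotypes
from priorgs.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_panel():
    """300 individuals x 1,500 SNPs, no missingness, 10 chromosomes."""
    return simulate_genotypes(300, 1500, seed=101)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    spec = TraitSpec(h2_true=0.3, rep_true=0.45, n_qtl=30, name="cy")
    records, truth = simulate_phenotypes(small_panel, spec, seed=202)
    return spec, records, truth


def make_geno(dosages, chrom=None, pos=None):
    """Hand-built GenotypeMatrix from a plain dosage list."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "id": [f"s{j+1}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 100 * (1 + np.arange(m)),
            "a1": "A",
            "a2": "B",
        }
    )
    ids = [f"i{k+1}" for k in range(n)]
    return GenotypeMatrix(dosages, np.array(ids, dtype=object), snps)
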