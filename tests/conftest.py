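import numpy as np
import pandas as pd
import pytest

from survfdr.datatypes import MISSING, GenotypeMatrix, PhenotypeVector


def make_genotypes(dosage, sample_ids=None, snp_ids=None, chrom="1"):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    meta = pd.DataFrame(
        {"id": snp_ids, "chrom": chrom, "pos": np.arange(1, m + 1), "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=meta, sample_ids=sample_ids)


@pytest.fixture
def toy_genotypes():
    """4 samples x 3 SNPs incl. one column with a missing call and one monomorphic."""
    return make_genotypes(
        [
            [0, 0, 0],
            [1, 0, 2],
            [2, 0, 2],
            [MISSING, 0, 2],
        ]
    )


@pytest.fixture
def small_phenotype():
    return PhenotypeVector(
        sample_ids=["s0", "s1", "s2", "s3"], values=[10.0, 20.0, 30.0, 40.0]
    )


@pytest.fixture
def outlier_phenotype():
    vals = list(np.linspace(0.1, 1.0, 10)) + [100.0]
    return PhenotypeVector(sample_ids=[f"g{i}" for i in range(11)], values=vals)
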