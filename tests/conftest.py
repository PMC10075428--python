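import numpy as np
import pandas as pd
import pytest

from rarefuse.io_formats import GenotypeDataset


def make_dataset(
    dosage,
    phenotype=None,
    sex=None,
    chromosomes=None,
    positions=None,
    sample_ids=None,
) -> GenotypeDataset:
    """Build a small GenotypeDataset from a dosage array with defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if phenotype is None:
        phenotype = np.full(n, -9, dtype=np.int8)
    if sex is None:
        sex = np.full(n, 0, dtype=np.int8)
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chromosome": list(chromosomes) if chromosomes is not None else ["1"] * m,
        "position": list(positions) if positions is not None else list(
            range(1000, 1000 * (m + 1), 1000)),
        "counted_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    return GenotypeDataset(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        sex=np.asarray(sex, dtype=np.int8),
        variants=variants,
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dataset(rng, n=50, m=100, maf_range=(0.1, 0.5), phenotype=None):
    p = rng.uniform(*maf_range, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_dataset(dosage, phenotype=phenotype)
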