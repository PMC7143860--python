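import numpy as np
import pandas as pd
import pytest

from roh_inbred.genotype_io import SNP_COLUMNS, GenotypeDataset


def make_dataset(calls, positions=None, chromosomes=None, samples=None,
                 allele_a="A", allele_b="C"):
    """Build a small GenotypeDataset from a call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_snps)]
    if chromosomes is None:
        chromosomes = [1] * n_snps
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )[SNP_COLUMNS]
    return GenotypeDataset(samples, snps, calls)


@pytest.fixture
def tiny_dataset():
    return make_dataset([[0, 1, 2, -1], [0, 0, 1, 2], [2, 1, 0, 0]])
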