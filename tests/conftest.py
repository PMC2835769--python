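import numpy as np
import pandas as pd
import pytest

from breedmap.genotype_io import GenotypeDataset


def make_dataset(
    calls,
    status=None,
    breeds=None,
    chromosomes=None,
    positions=None,
    sample_ids=None,
):
    """Build a small GenotypeDataset from a calls matrix and defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if status is None:
        status = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    if breeds is None:
        breeds = [f"B{i + 1}" for i in range(n)]
    if sample_ids is None:
        sample_ids = [f"dog{i + 1}" for i in range(n)]
    if chromosomes is None:
        chromosomes = ["1"] * s
    if positions is None:
        pos_counter = {}
        positions = []
        for c in chromosomes:
            pos_counter[c] = pos_counter.get(c, 0) + 1000
            positions.append(pos_counter[c])
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "breed": breeds, "status": status}
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"Chr{c}.{p}" for c, p in zip(chromosomes, positions)],
            "chromosome": chromosomes,
            "position_bp": positions,
        }
    )
    return GenotypeDataset(calls, samples, snps)


def random_dataset(rng, n_samples, n_snps, missing_rate=0.0, n_chromosomes=1):
    """Random small dataset with genotypes drawn per SNP from HWE."""
    freqs = rng.uniform(0.1, 0.9, n_snps)
    haps = rng.random((2 * n_samples, n_snps)) < freqs
    calls = (haps[0::2].astype(int) + haps[1::2]).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(
            rng.random(calls.shape) < missing_rate, -1, calls
        ).astype(np.int8)
    chromosomes = [
        str(1 + (j * n_chromosomes) // n_snps) for j in range(n_snps)
    ]
    return make_dataset(calls, chromosomes=chromosomes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
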