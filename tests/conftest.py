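import numpy as np
import pandas as pd
import pytest

from snpruns.genotypes import GenomicMap, GenotypeMatrix


def make_matrix(rows, positions, chrom="1", breeds=None, samples=None,
                start_id=0):
    """Build a GenotypeMatrix from code strings.

    ``rows`` are strings over {0,1,2,M} (M = missing), one per sample;
    ``positions`` the 1-based bp positions (one chromosome unless
    ``chrom`` is a list parallel to positions).
    """
    decode = {"0": 0, "1": 1, "2": 2, "M": -1}
    calls = np.array([[decode[c] for c in row] for row in rows],
                     dtype=np.int8)
    n_snps = calls.shape[1]
    chroms = [chrom] * n_snps if isinstance(chrom, str) else list(chrom)
    gmap = GenomicMap(pd.DataFrame({
        "snp_id": [f"s{start_id + j}" for j in range(n_snps)],
        "chrom": chroms,
        "pos": list(positions),
    }))
    samples = samples or [f"ind{i}" for i in range(len(rows))]
    breeds = breeds or ["B0"] * len(rows)
    return GenotypeMatrix(samples, breeds, gmap, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
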