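import numpy as np
import pandas as pd
import pytest

from wprskit.datatypes import MISSING, GenotypeMatrix, VariantMeta, WeightTable

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


def make_matrix(dosages, chrom="1", start_pos=100, prefix="rs") -> GenotypeMatrix:
    """GenotypeMatrix from a plain nested list / array of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = [
        VariantMeta(
            chrom=chrom,
            pos=start_pos + 10 * j,
            vid=f"{prefix}{j}",
            allele_counted=ALLELE_PAIRS[j % len(ALLELE_PAIRS)][0],
            allele_other=ALLELE_PAIRS[j % len(ALLELE_PAIRS)][1],
        )
        for j in range(m)
    ]
    return GenotypeMatrix(dosages, variants, [f"S{i}" for i in range(n)])


def random_matrix(rng, n=20, m=31, missing_rate=0.05) -> GenotypeMatrix:
    maf = rng.uniform(0.1, 0.5, size=m)
    dos = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    if missing_rate:
        dos[rng.random((n, m)) < missing_rate] = MISSING
    return make_matrix(dos)


def weights_for(gm: GenotypeMatrix, weights=None, rng=None) -> WeightTable:
    """Weight table matching a matrix's variants (effect = counted allele)."""
    m = gm.n_variants
    if weights is None:
        weights = rng.normal(0.4, 0.2, size=m) if rng is not None else np.ones(m)
    return WeightTable(
        pd.DataFrame(
            {
                "vid": gm.vids,
                "effect_allele": [v.allele_counted for v in gm.variants],
                "other_allele": [v.allele_other for v in gm.variants],
                "weight": np.asarray(weights, float),
                "source": ["gwas"] * m,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
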