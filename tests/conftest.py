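import numpy as np
import pandas as pd
import pytest

from ssblup.pedigree import Pedigree


def make_random_pedigree(n, seed, p_founder=0.2, genotyped=None):
    """Random valid pedigree: each non-founder draws parents among earlier
    animals (ids 1..n in order, so always acyclic)."""
    rng = np.random.default_rng(seed)
    recs = [(1, 0, 0), (2, 0, 0)]
    for i in range(3, n + 1):
        if rng.random() < p_founder:
            recs.append((i, 0, 0))
        else:
            s = int(rng.integers(1, i))
            d = int(rng.integers(1, i))
            if s == d:
                d = 0
            recs.append((i, s, d))
    return Pedigree.from_records(recs, genotyped=genotyped or ())


def make_genotypes(n_animals, n_markers, seed, freq=None):
    """Binomial(2, p) genotype matrix with a simple one-chromosome map."""
    rng = np.random.default_rng(seed)
    p = freq if freq is not None else rng.uniform(0.1, 0.9, n_markers)
    M = rng.binomial(2, p, size=(n_animals, n_markers)).astype(float)
    markers = pd.DataFrame(
        {"marker": [f"m{j}" for j in range(n_markers)], "chrom": 1,
         "pos": np.arange(n_markers, dtype=float)}
    )
    return M, markers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
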