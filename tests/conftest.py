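import numpy as np
import pandas as pd
import pytest

from wtme.io import ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_log_matrix(rng):
    """12 genes x 4 samples on the log2TPM scale."""
    genes = [f"g{i:02d}" for i in range(12)]
    samples = [f"s{j}" for j in range(4)]
    vals = pd.DataFrame(rng.uniform(0, 10, size=(12, 4)), index=genes, columns=samples)
    return ExpressionMatrix(vals, "log2TPM")


@pytest.fixture
def two_sets():
    return GeneSetCollection(
        {"setA": ["g00", "g03", "g07"], "setB": ["g01", "g02", "g10", "g11"]}
    )


def brute_force_ssgsea(values: pd.Series, gene_set: list[str], alpha: float) -> float:
    """Independent ssGSEA oracle: materialize both cumulative curves stepwise.

    Walks the descending expression ranking gene by gene, maintaining the
    weighted in-set and unweighted out-set cumulative fractions explicitly.
    """
    ordered = sorted(values.index, key=lambda g: (-values[g], g))
    n = len(ordered)
    in_set = set(gene_set) & set(values.index)
    n_out = n - len(in_set)
    weights = {g: (n - i) ** alpha for i, g in enumerate(ordered)}  # pos i is 0-based
    total_w = sum(weights[g] for g in in_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in ordered:
        if g in in_set:
            cum_in += weights[g]
        else:
            cum_out += 1
        p_in = cum_in / total_w if total_w > 0 else 0.0
        p_out = cum_out / n_out if n_out > 0 else 0.0
        es += p_in - p_out
    return es
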