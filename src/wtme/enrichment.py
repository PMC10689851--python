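"""Single-sample signature scoring.

The per-sample enrichment score (ssGSEA) for a gene set is the area between
two cumulative curves walked down the sample's expression ranking: the
rank-weighted cumulative fraction of in-set genes minus the unweighted
cumulative fraction of out-set genes,

    ES = sum_i [ P_in^w(i) - P_out(i) ],     w_j = (N - pos_j + 1)^alpha

where genes are ordered by descending expression (ties broken ordinally by
gene id), pos_j is a gene's 1-based position in that ordering, and alpha
weights highly expressed in-set genes more.  Being rank-based, scores are
invariant to any monotone transform of a sample's expression values.

The microenvironment profile divides each cell type's score by
(1 - tumor purity): two samples with the same non-tumor composition but
different purity then get comparable abundance estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from wtme.io import ExpressionMatrix, GeneSetCollection, ScaleError


@dataclass
class EnrichmentParams:
    """Scoring parameters.

    alpha : rank-weight exponent (>= 0). 0.25 is the common ssGSEA default.
    normalize : divide all scores by the profile-wide (max - min).
    """

    alpha: float = 0.25
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


@dataclass
class EnrichmentProfile:
    """Sample x gene-set score table plus the parameters that produced it."""

    scores: pd.DataFrame  # samples x sets
    params: EnrichmentParams
    adjusted: bool = False
    dropped_genes: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)


def _sample_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering one sample's genes by descending value, ties by gene id."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -values))


def _es_single(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ES for one sample given the descending ordering and in-set mask."""
    n = order.size
    mask = in_set[order]
    n_in = int(mask.sum())
    n_out = n - n_in
    if n_in == 0 or n_out == 0:
        # Degenerate set (everything or nothing): both curves coincide.
        return 0.0
    pos = np.arange(1, n + 1, dtype=float)
    w = (n - pos + 1.0) ** alpha
    w_in = np.where(mask, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~mask) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> EnrichmentProfile:
    """Score every gene set in every sample.

    Set genes absent from the matrix are dropped with a warning (the count is
    recorded on the profile); a set with no gene in the matrix is an error.
    """
    if m.scale != "log2TPM":
        raise ScaleError(f"expected log2TPM, got {m.scale}")
    params = params or EnrichmentParams()
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    masks: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    for name, genes in sets.items():
        present = [gene_index[g] for g in genes if g in gene_index]
        n_drop = len(genes) - len(present)
        if not present:
            raise ValueError(f"gene set {name!r} shares no gene with the matrix")
        if n_drop:
            dropped[name] = n_drop
            warnings.warn(
                f"gene set {name!r}: {n_drop} gene(s) absent from matrix, dropped",
                stacklevel=2,
            )
        mask = np.zeros(m.n_genes, dtype=bool)
        mask[present] = True
        masks[name] = mask

    gene_ids = np.asarray(m.gene_ids)
    values = m.values.to_numpy(dtype=float)
    scores = np.empty((m.n_samples, len(masks)))
    for j in range(m.n_samples):
        order = _sample_order(values[:, j], gene_ids)
        for k, mask in enumerate(masks.values()):
            scores[j, k] = _es_single(order, mask, params.alpha)

    df = pd.DataFrame(scores, index=m.sample_ids, columns=list(masks))
    if params.normalize:
        span = float(df.to_numpy().max() - df.to_numpy().min())
        if span > 0:
            df = df / span
    return EnrichmentProfile(df, params, adjusted=False, dropped_genes=dropped)


def adjust_for_purity(
    profile: EnrichmentProfile, purity: Mapping[str, float]
) -> EnrichmentProfile:
    """Divide each sample's scores by (1 - tumor purity)."""
    factors = []
    for s in profile.sample_ids:
        if s not in purity:
            raise ValueError(f"no purity for sample {s!r}")
        p = float(purity[s])
        if p >= 1.0:
            raise ValueError(f"sample {s!r} has purity {p} >= 1; adjustment undefined")
        if p < 0.0:
            raise ValueError(f"sample {s!r} has negative purity {p}")
        factors.append(1.0 - p)
    adj = profile.scores.div(pd.Series(factors, index=profile.sample_ids), axis=0)
    return EnrichmentProfile(
        adj, profile.params, adjusted=True, dropped_genes=dict(profile.dropped_genes)
    )


def geometric_mean_signature(
    m: ExpressionMatrix, gene_set: list[str], offset: float = 1.0
) -> pd.Series:
    """Geometric-mean signature score (used for the TLS signature).

    Per sample: exp(mean(log(TPM + offset))) - offset over the set genes.
    The offset (default 1) keeps a single zero-TPM gene from annihilating
    the product.
    """
    if m.scale != "TPM":
        raise ScaleError(f"expected TPM, got {m.scale}")
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in m.values.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing[:5]}")
    sub = m.values.loc[gene_set].to_numpy(dtype=float)
    score = np.exp(np.mean(np.log(sub + offset), axis=0)) - offset
    return pd.Series(score, index=m.sample_ids, name="geometric_mean")
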