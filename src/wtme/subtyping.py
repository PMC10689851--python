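"""Consensus clustering into microenvironment phenotypes and cross-cohort
subclass mapping.

Consensus clustering repeatedly subsamples features and samples (default
90% of each, 500 perturbations), hierarchically clusters each subsample
with 1 - Pearson correlation distance and Ward linkage, and records for
every sample pair how often they co-cluster among the perturbations that
drew them together.  Final labels come from hierarchically clustering
1 - consensus with the same linkage.  For k = 2 microenvironment profiles
the cluster with lower mean cell-type enrichment is named "dWT"
(desert-like) and the other "iWT" (infiltrated-like).

Subclass mapping assesses whether subtypes found independently in two
cohorts are transcriptomically the same: for each subclass pair, each
cohort's top signal-to-noise marker genes are scored against the other
cohort's subclass-vs-rest contrast, with a label-permutation null in each
direction; the pair's p-value is the worse (max) of the two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from wtme.enrichment import EnrichmentProfile
from wtme.io import ExpressionMatrix
from wtme.stats import bh_fdr


@dataclass
class ConsensusParams:
    k: int = 2
    n_perturbations: int = 500
    feature_fraction: float = 0.9
    sample_fraction: float = 0.9
    linkage_method: str = "ward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        for name in ("feature_fraction", "sample_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class SubtypeAssignment:
    """Consensus matrix, per-sample labels and (optionally) phenotype names."""

    consensus_matrix: pd.DataFrame  # sample x sample co-clustering frequency
    labels: pd.Series  # sample -> cluster id (1..k, decreasing size)
    params: ConsensusParams
    phenotype_names: dict[int, str] | None = None  # cluster id -> iWT/dWT
    naming_margin: float | None = None
    unresolved: bool = False

    @property
    def phenotypes(self) -> pd.Series:
        """Per-sample phenotype names (requires :func:`name_phenotypes`)."""
        if self.phenotype_names is None:
            raise ValueError("phenotypes not yet named; run name_phenotypes first")
        return self.labels.map(self.phenotype_names)


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get distance 1."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    corr = (xc / safe[:, None]) @ (xc / safe[:, None]).T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return 1.0 - np.clip(corr, -1.0, 1.0)


def _hcluster(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    return fcluster(z, t=k, criterion="maxclust")


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Cluster ids 1..k by decreasing size; ties by first sample index."""
    ids, first_idx = np.unique(labels, return_index=True)
    sizes = np.array([(labels == i).sum() for i in ids])
    order = sorted(range(len(ids)), key=lambda j: (-sizes[j], first_idx[j]))
    mapping = {ids[j]: rank + 1 for rank, j in enumerate(order)}
    return np.array([mapping[l] for l in labels])


class ConsensusClusterer:
    """Resampling-based consensus clustering (fit -> :class:`SubtypeAssignment`)."""

    def __init__(self, params: ConsensusParams | None = None, **kwargs):
        self.params = params or ConsensusParams(**kwargs)

    def fit(self, features: pd.DataFrame) -> SubtypeAssignment:
        """Cluster samples (rows) described by feature columns."""
        p = self.params
        n, m = features.shape
        if n < p.k:
            raise ValueError(f"need >= k={p.k} samples, got {n}")
        if m < 2:
            raise ValueError(f"need >= 2 features, got {m}")
        x = features.to_numpy(dtype=float)
        rng = np.random.default_rng(p.seed)
        n_s = max(p.k, math.ceil(p.sample_fraction * n))
        n_f = max(1, math.ceil(p.feature_fraction * m))

        together = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(p.n_perturbations):
            si = np.sort(rng.choice(n, size=n_s, replace=False))
            fi = np.sort(rng.choice(m, size=n_f, replace=False))
            sub = x[np.ix_(si, fi)]
            labels = _hcluster(_pearson_distance(sub), p.k, p.linkage_method)
            co_sampled[np.ix_(si, si)] += 1
            same = labels[:, None] == labels[None, :]
            together[np.ix_(si, si)] += same

        isolated = [
            features.index[i]
            for i in range(n)
            if (co_sampled[i].sum() - co_sampled[i, i]) == 0
        ]
        if isolated:
            raise ValueError(
                f"samples never co-sampled with any other: {isolated[:5]}; "
                "increase n_perturbations or sample_fraction"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2

        final = _hcluster(1.0 - consensus, p.k, p.linkage_method)
        final = _relabel_by_size(final)
        return SubtypeAssignment(
            pd.DataFrame(consensus, index=features.index, columns=features.index),
            pd.Series(final, index=features.index, name="cluster"),
            p,
        )


def consensus_cluster(
    features: pd.DataFrame, params: ConsensusParams | None = None, **kwargs
) -> SubtypeAssignment:
    """Functional wrapper around :class:`ConsensusClusterer`."""
    return ConsensusClusterer(params, **kwargs).fit(features)


def name_phenotypes(
    assignment: SubtypeAssignment, profile: EnrichmentProfile
) -> SubtypeAssignment:
    """Name the k=2 clusters by overall microenvironment abundance.

    The cluster with the lower mean enrichment across all cell types is the
    desert-like phenotype (dWT), the other infiltrated-like (iWT).  Exactly
    equal means are flagged unresolved, never guessed.
    """
    k = assignment.params.k
    if k != 2:
        raise ValueError(f"phenotype naming requires k=2, got k={k}")
    missing = [s for s in assignment.labels.index if s not in profile.scores.index]
    if missing:
        raise ValueError(f"profile missing samples: {missing[:5]}")
    means = {
        cid: float(profile.scores.loc[idx].to_numpy().mean())
        for cid, idx in assignment.labels.groupby(assignment.labels).groups.items()
    }
    (c1, m1), (c2, m2) = sorted(means.items())
    margin = abs(m1 - m2)
    if m1 == m2:
        assignment.phenotype_names = None
        assignment.unresolved = True
        assignment.naming_margin = 0.0
        return assignment
    low, high = (c1, c2) if m1 < m2 else (c2, c1)
    assignment.phenotype_names = {low: "dWT", high: "iWT"}
    assignment.naming_margin = margin
    assignment.unresolved = False
    return assignment


# ---------------------------------------------------------------------------
# Subclass mapping between cohorts
# ---------------------------------------------------------------------------


@dataclass
class SubclassMapResult:
    """Association p-values between cohort-A and cohort-B subclasses."""

    p_values: pd.DataFrame  # A subclasses x B subclasses
    bonferroni: pd.DataFrame
    bh: pd.DataFrame
    n_marker_genes: int
    n_permutations: int
    seed: int


def _snr_contrast(x: np.ndarray, in_group: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Signal-to-noise ratio per gene: (mean_in - mean_rest)/(sd_in + sd_rest)."""
    a = x[:, in_group]
    b = x[:, ~in_group]
    return (a.mean(axis=1) - b.mean(axis=1)) / (
        a.std(axis=1, ddof=0) + b.std(axis=1, ddof=0) + eps
    )


def subclass_map(
    expr_a: ExpressionMatrix,
    labels_a: pd.Series,
    expr_b: ExpressionMatrix,
    labels_b: pd.Series,
    n_marker_genes: int = 50,
    n_permutations: int = 200,
    seed: int = 0,
) -> SubclassMapResult:
    """Mutual marker-gene association between two cohorts' subclasses.

    For subclasses (a, b): direction a->b takes a's top ``n_marker_genes``
    SNR markers (computed in A over the shared gene universe) and scores
    their mean SNR in B's b-vs-rest contrast, against a null that permutes
    B's labels; direction b->a mirrors this.  The pair's p is the max of
    the two directional permutation p-values, adjusted two ways (Bonferroni
    and BH) over all pairs.
    """
    labels_a = pd.Series(labels_a)
    labels_b = pd.Series(labels_b)
    shared = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    if not shared:
        raise ValueError("empty shared gene universe")
    subs_a = sorted(labels_a.unique())
    subs_b = sorted(labels_b.unique())
    if len(subs_a) < 2 or len(subs_b) < 2:
        raise ValueError("need >= 2 subclasses per cohort")
    for name, labels in (("A", labels_a), ("B", labels_b)):
        small = labels.value_counts()
        if (small < 2).any():
            raise ValueError(f"cohort {name} has a subclass with < 2 samples")

    xa = expr_a.values.loc[shared, list(labels_a.index)].to_numpy(dtype=float)
    xb = expr_b.values.loc[shared, list(labels_b.index)].to_numpy(dtype=float)
    la = labels_a.to_numpy()
    lb = labels_b.to_numpy()
    rng = np.random.default_rng(seed)

    def directional_p(
        x_src, l_src, src_class, x_dst, l_dst, dst_class
    ) -> float:
        snr_src = _snr_contrast(x_src, l_src == src_class)
        markers = np.argsort(-snr_src, kind="stable")[:n_marker_genes]
        obs = float(_snr_contrast(x_dst, l_dst == dst_class)[markers].mean())
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(l_dst)
            stat = float(_snr_contrast(x_dst, perm == dst_class)[markers].mean())
            if stat >= obs:
                exceed += 1
        return (1 + exceed) / (n_permutations + 1)

    p = pd.DataFrame(index=subs_a, columns=subs_b, dtype=float)
    for a in subs_a:
        for b in subs_b:
            p_ab = directional_p(xa, la, a, xb, lb, b)
            p_ba = directional_p(xb, lb, b, xa, la, a)
            p.loc[a, b] = max(p_ab, p_ba)

    flat = p.to_numpy().ravel()
    bonf = np.minimum(flat * flat.size, 1.0)
    bh = bh_fdr(flat)
    shape = p.shape
    return SubclassMapResult(
        p,
        pd.DataFrame(bonf.reshape(shape), index=subs_a, columns=subs_b),
        pd.DataFrame(bh.reshape(shape), index=subs_a, columns=subs_b),
        n_marker_genes,
        n_permutations,
        seed,
    )
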