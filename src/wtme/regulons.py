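"""Regulon inference and per-sample regulon activity.

A regulon is a candidate regulator plus its inferred signed target set.
Inference follows the mutual-information network recipe: (1) MI between
each regulator and every other gene, with the association sign from
Spearman correlation; (2) a sample-permutation null per regulator, BH FDR
across all candidate edges, keeping edges below an FDR threshold;
(3) bootstrap resampling of samples, keeping only edges recovered in more
than a consensus fraction of resamples; (4) data-processing-inequality
(DPI) pruning, removing the weakest edge of every regulator-regulator-
target triangle unless within a tolerance of the second weakest.

The MI estimator is deliberately simple and deterministic: equal-frequency
binning into ceil(sqrt(n_samples)) bins per gene.

Per-sample activity of a regulon is a two-tailed enrichment: genes are
ranked by the sample's centered expression, and activity is the running-sum
enrichment of positive targets minus that of negative targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import mutual_info_score

from wtme.io import ExpressionMatrix
from wtme.stats import bh_fdr, enrichment_running_sum, _es_from_running

MIN_SAMPLES = 8


@dataclass
class Edge:
    regulator: str
    target: str
    sign: int  # +1 / -1 from Spearman correlation
    strength: float  # mutual information


@dataclass
class RegulonNetwork:
    edges: list[Edge]
    params: dict = field(default_factory=dict)

    def targets(self, regulator: str) -> dict[str, int]:
        return {e.target: e.sign for e in self.edges if e.regulator == regulator}

    @property
    def regulators(self) -> list[str]:
        return sorted({e.regulator for e in self.edges})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.regulator, e.target, "+" if e.sign > 0 else "-", e.strength) for e in self.edges],
            columns=["regulator", "target", "sign", "strength"],
        )


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning (deterministic, average ties)."""
    ranks = sps.rankdata(x, method="average") - 1  # 0..n-1
    return np.minimum((ranks * n_bins / x.size).astype(int), n_bins - 1)


def _mi(bx: np.ndarray, by: np.ndarray) -> float:
    return float(mutual_info_score(bx, by))


def infer_regulons(
    m: ExpressionMatrix,
    regulators: list[str],
    fdr_threshold: float = 0.01,
    n_bootstrap: int = 1000,
    consensus_min: float = 0.95,
    dpi_tolerance: float = 0.0,
    n_permutations: int = 100,
    seed: int = 0,
) -> RegulonNetwork:
    """Infer signed regulator -> target edges from an expression matrix."""
    missing = [r for r in regulators if r not in m.values.index]
    if missing:
        raise ValueError(f"regulators absent from matrix: {missing[:5]}")
    if m.n_samples < MIN_SAMPLES:
        raise ValueError(
            f"need >= {MIN_SAMPLES} samples for the MI estimator, got {m.n_samples}"
        )
    x = m.values.to_numpy(dtype=float)
    genes = list(m.gene_ids)
    gidx = {g: i for i, g in enumerate(genes)}
    n = m.n_samples
    n_bins = math.ceil(math.sqrt(n))
    rng = np.random.default_rng(seed)

    binned = np.vstack([_equal_frequency_bins(x[i], n_bins) for i in range(len(genes))])

    # (1) observed MI + sign, and (2) per-regulator permutation null
    candidates: list[Edge] = []
    p_values: list[float] = []
    null_q95: dict[str, float] = {}
    for reg in regulators:
        ri = gidx[reg]
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            null[b] = _mi(binned[ri][rng.permutation(n)], binned[ri])
        # null distribution of MI against an unrelated profile: permute the
        # regulator, score against every gene is costly; one partner suffices
        # because the MI null depends only on the margins (equal-frequency bins).
        null_q95[reg] = float(np.quantile(null, 0.95))
        for g in genes:
            if g == reg:
                continue
            mi = _mi(binned[ri], binned[gidx[g]])
            rho = sps.spearmanr(x[ri], x[gidx[g]]).statistic
            sign = 1 if (rho >= 0 or np.isnan(rho)) else -1
            candidates.append(Edge(reg, g, sign, mi))
            p_values.append((1 + np.sum(null >= mi)) / (n_permutations + 1))

    q = bh_fdr(p_values)
    kept = [e for e, qv in zip(candidates, q) if qv < fdr_threshold]

    # (3) bootstrap consensus: an edge must beat the null 95th percentile in
    # more than consensus_min of the resamples
    if kept and n_bootstrap > 0:
        counts = np.zeros(len(kept))
        for _ in range(n_bootstrap):
            bs = rng.integers(0, n, size=n)
            xb = x[:, bs]
            bb = {}
            for j, e in enumerate(kept):
                for g in (e.regulator, e.target):
                    if g not in bb:
                        bb[g] = _equal_frequency_bins(xb[gidx[g]], n_bins)
                if _mi(bb[e.regulator], bb[e.target]) > null_q95[e.regulator]:
                    counts[j] += 1
        kept = [e for e, c in zip(kept, counts) if c / n_bootstrap > consensus_min]

    # (4) DPI pruning over regulator-regulator-target triangles
    strength = {(e.regulator, e.target): e.strength for e in kept}

    def edge_strength(a: str, b: str) -> float | None:
        s = strength.get((a, b))
        if s is None:
            s = strength.get((b, a))
        return s

    reg_set = [r for r in regulators if any(e.regulator == r for e in kept)]
    to_remove: set[tuple[str, str]] = set()
    for i, r1 in enumerate(reg_set):
        for r2 in reg_set[i + 1 :]:
            rr = edge_strength(r1, r2)
            if rr is None:
                continue
            t1 = {e.target for e in kept if e.regulator == r1}
            t2 = {e.target for e in kept if e.regulator == r2}
            for t in t1 & t2:
                s1 = strength[(r1, t)]
                s2 = strength[(r2, t)]
                triple = sorted(
                    [((r1, t), s1), ((r2, t), s2), ((min(r1, r2), max(r1, r2)), rr)],
                    key=lambda kv: kv[1],
                )
                weakest, second = triple[0], triple[1]
                if weakest[1] < second[1] - dpi_tolerance:
                    key = weakest[0]
                    if key == (min(r1, r2), max(r1, r2)):
                        # regulator-regulator edge; stored under whichever direction exists
                        if (r1, r2) in strength:
                            to_remove.add((r1, r2))
                        if (r2, r1) in strength:
                            to_remove.add((r2, r1))
                    else:
                        to_remove.add(key)
    pruned = [e for e in kept if (e.regulator, e.target) not in to_remove]

    params = {
        "fdr_threshold": fdr_threshold,
        "n_bootstrap": n_bootstrap,
        "consensus_min": consensus_min,
        "dpi_tolerance": dpi_tolerance,
        "n_permutations": n_permutations,
        "n_bins": n_bins,
        "seed": seed,
    }
    return RegulonNetwork(pruned, params)


def regulon_activity(
    network: RegulonNetwork, m: ExpressionMatrix, weight: float = 1.0
) -> pd.DataFrame:
    """Two-tailed enrichment activity of each regulon in each sample.

    Genes are ranked per sample by expression centered on the gene's
    cohort mean (so activity reflects relative over/under-expression);
    activity = ES(positive targets) - ES(negative targets).
    Regulons with no targets in the matrix are skipped with a warning.
    """
    if not network.edges:
        raise ValueError("empty regulon network")
    x = m.values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    gene_ids = np.asarray(m.gene_ids)

    cols = {}
    for reg in network.regulators:
        tgt = network.targets(reg)
        present = {g: s for g, s in tgt.items() if g in set(m.gene_ids)}
        if not present:
            warnings.warn(f"regulon {reg!r} has no targets in the matrix; skipped")
            continue
        gindex = {g: i for i, g in enumerate(m.gene_ids)}
        pos = np.zeros(len(gene_ids), dtype=bool)
        neg = np.zeros(len(gene_ids), dtype=bool)
        for g, s in present.items():
            (pos if s > 0 else neg)[gindex[g]] = True
        n_genes = len(gene_ids)
        # centered ranks as the running-sum scores keep the statistic purely
        # rank-based: any order-preserving change to a sample leaves it fixed
        rank_scores = np.arange(n_genes, 0, -1, dtype=float) - (n_genes + 1) / 2
        acts = np.zeros(m.n_samples)
        for j in range(m.n_samples):
            order = np.lexsort((gene_ids, -centered[:, j]))
            a = 0.0
            if pos.any():
                a += _es_from_running(enrichment_running_sum(rank_scores, pos[order], weight))
            if neg.any():
                a -= _es_from_running(enrichment_running_sum(rank_scores, neg[order], weight))
            acts[j] = a
        cols[reg] = acts
    if not cols:
        raise ValueError("no regulon overlapped the matrix")
    return pd.DataFrame(cols, index=m.sample_ids)
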