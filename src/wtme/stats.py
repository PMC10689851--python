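"""Cross-cutting statistics.

- representation factor (RF): the observed overlap of two gene sets divided
  by the overlap expected under independence, k / (m*n/N), with an exact
  hypergeometric tail probability;
- a rank-based differential-expression statistic (mean log2 fold change +
  exact Mann-Whitney p + Benjamini-Hochberg FDR) and the strict
  fold-change/p/FDR threshold filter;
- pre-ranked GSEA: the classic weighted Kolmogorov-Smirnov running-sum
  enrichment score with a gene-label permutation null.

The differential-expression statistic here is a deliberate, documented
stand-in for count-model DE (negative-binomial GLMs): it needs only the
log-scale matrix, is exact at small n, and feeds the same downstream
threshold filter and pre-ranked GSEA.  Its gene lists are not expected to
match count-model lists gene-for-gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from wtme.io import ExpressionMatrix, GeneSetCollection, ScaleError

# ---------------------------------------------------------------------------
# Representation factor
# ---------------------------------------------------------------------------

#: Above this universe size the hypergeometric tail switches to a normal
#: approximation; genome-scale universes (~2e4 genes) always use the exact tail.
NORMAL_APPROX_CUTOFF = 1_000_000


@dataclass
class OverlapResult:
    """Overlap of two gene sets of sizes m and n drawn from a universe of N."""

    m: int
    n: int
    k: int
    N: int
    expected: float
    rf: float
    p: float
    method: str  # "exact" or "normal"

    def __str__(self) -> str:  # RF reported to one decimal, field convention
        return f"RF = {self.rf:.1f} (k={self.k}, expected={self.expected:.1f}, P={self.p:.3g}, {self.method})"


def representation_factor(m: int, n: int, k: int, N: int) -> OverlapResult:
    """Representation factor and hypergeometric enrichment p-value.

    RF = k / (m*n/N); p = P(X >= k) for X ~ Hypergeometric(N, m, n).
    RF > 1 means more overlap than independent sets would give.
    """
    if min(m, n, k, N) < 0:
        raise ValueError("set sizes must be nonnegative")
    if k > min(m, n):
        raise ValueError(f"overlap k={k} exceeds min(m,n)={min(m, n)}")
    if N < max(m, n):
        raise ValueError(f"universe N={N} smaller than a set ({max(m, n)})")
    if m == 0 or n == 0:
        raise ValueError("empty gene set: RF undefined")
    expected = m * n / N
    rf = k / expected
    if N > NORMAL_APPROX_CUTOFF:
        mu = expected
        var = expected * (N - m) * (N - n) / (N * (N - 1))
        # continuity-corrected upper tail
        p = float(sps.norm.sf((k - 0.5 - mu) / np.sqrt(var)))
        method = "normal"
    else:
        p = float(sps.hypergeom.sf(k - 1, N, m, n))
        method = "exact"
    return OverlapResult(m, n, k, N, expected, rf, min(p, 1.0), method)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Step-up BH adjustment; q-values returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression stand-in + threshold filter
# ---------------------------------------------------------------------------


def differential_expression(
    m: ExpressionMatrix, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-gene group-2-vs-group-1 contrast on the log2 matrix.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (difference
    of group means on the log2 scale, group 2 minus group 1), ``p`` (exact
    two-sided Mann-Whitney where sample sizes permit) and ``q`` (BH FDR).
    """
    if m.scale != "log2TPM":
        raise ScaleError(f"expected log2TPM, got {m.scale}")
    groups = pd.Series(groups)
    g1 = [s for s in m.sample_ids if groups.get(s) == 1]
    g2 = [s for s in m.sample_ids if groups.get(s) == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(g1)} and {len(g2)}"
        )
    x1 = m.values[g1].to_numpy(dtype=float)
    x2 = m.values[g2].to_numpy(dtype=float)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    ps = np.empty(m.n_genes)
    for i in range(m.n_genes):
        if np.all(x2[i] == x2[i][0]) and np.all(x1[i] == x1[i][0]) and x1[i][0] == x2[i][0]:
            ps[i] = 1.0
            continue
        ps[i] = sps.mannwhitneyu(
            x2[i], x1[i], alternative="two-sided", method="auto"
        ).pvalue
    return pd.DataFrame(
        {"log2fc": log2fc, "p": ps, "q": bh_fdr(ps)}, index=m.gene_ids
    )


def threshold_de(
    de: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    q_max: float = 0.25,
) -> tuple[set, set]:
    """Strict-inequality threshold filter.

    up: FC > fc_min; down: FC < 1/fc_min; both also require p < p_max and
    q < q_max.  A gene at FC exactly fc_min is excluded.
    """
    if min(fc_min, p_max, q_max) <= 0:
        raise ValueError("thresholds must be positive")
    if de.empty:
        return set(), set()
    fc = np.exp2(de["log2fc"].to_numpy(dtype=float))
    ok = (de["p"].to_numpy() < p_max) & (de["q"].to_numpy() < q_max)
    up = set(de.index[(fc > fc_min) & ok])
    down = set(de.index[(fc < 1.0 / fc_min) & ok])
    return up, down


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------


def enrichment_running_sum(
    ordered_scores: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> np.ndarray:
    """Running-sum curve of the weighted KS statistic.

    ``ordered_scores`` must already be in descending-rank order and
    ``in_set`` is the aligned membership mask.  In-set genes advance the sum
    by |score|^weight (normalized); out-of-set genes retreat it by
    1/(N - n_in).
    """
    n = ordered_scores.size
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        return np.zeros(n)
    w = np.abs(ordered_scores) ** weight
    inc = np.where(in_set, w, 0.0)
    denom = inc.sum()
    if denom == 0:  # all in-set scores are zero: fall back to equal steps
        inc = in_set.astype(float)
        denom = float(n_in)
    steps = inc / denom - (~in_set) / (n - n_in)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> float:
    """Signed maximal deviation of the running sum from zero."""
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class GseaSetResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    n_genes: int


@dataclass
class GseaResult:
    """Per-set enrichment results from a pre-ranked run."""

    table: pd.DataFrame  # index set name; columns es, nes, p, q, n_genes
    n_permutations: int
    seed: int


def preranked_gsea(
    ranked_scores: pd.Series | dict,
    sets: GeneSetCollection,
    n_permutations: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Classic pre-ranked GSEA with a gene-label permutation null.

    Genes are ordered by descending score (ties by gene id); for each set
    the ES is the signed maximal deviation of the running sum.  The null
    re-draws the set's positions uniformly (gene-label permutation); NES is
    ES divided by the mean |permuted ES| of the same sign, the nominal p is
    the same-sign permutation tail, and q is BH over the sets' nominal p.
    """
    scores = pd.Series(ranked_scores, dtype=float)
    if scores.index.has_duplicates:
        raise ValueError("ranked gene list has duplicate genes")
    order = sorted(zip(scores.index, scores.to_numpy()), key=lambda t: (-t[1], t[0]))
    genes = np.asarray([g for g, _ in order])
    vals = np.asarray([v for _, v in order], dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            warnings.warn(f"gene set {name!r} has no overlap with the ranked list, skipped")
            continue
        mask = np.zeros(genes.size, dtype=bool)
        mask[idx] = True
        es = _es_from_running(enrichment_running_sum(vals, mask, weight))
        null = np.empty(n_permutations)
        n_in = len(idx)
        for b in range(n_permutations):
            perm = np.zeros(genes.size, dtype=bool)
            perm[rng.choice(genes.size, size=n_in, replace=False)] = True
            null[b] = _es_from_running(enrichment_running_sum(vals, perm, weight))
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes = 0.0
            p = 1.0 / (n_permutations + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (same_sign.size + 1)
        rows.append({"name": name, "es": es, "nes": nes, "p": p, "n_genes": n_in})

    table = pd.DataFrame(rows).set_index("name") if rows else pd.DataFrame(
        columns=["es", "nes", "p", "n_genes"]
    )
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        table["q"] = []
    return GseaResult(table[["es", "nes", "p", "q", "n_genes"]], n_permutations, seed)


# ---------------------------------------------------------------------------
# Exact small-n tests used throughout the analyses
# ---------------------------------------------------------------------------


def fisher_exact_onesided(table, alternative: str = "greater") -> float:
    """One-sided Fisher exact p for a 2x2 table (hypergeometric tail)."""
    return float(sps.fisher_exact(np.asarray(table), alternative=alternative)[1])


def fisher_exact_twosided(table) -> float:
    """Two-sided Fisher exact p: sum of tables with probability <= observed."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def mannwhitney_exact(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p (enumeration of rank splits; ties -> asymptotic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if np.unique(np.concatenate([x, y])).size == x.size + y.size else "auto"
    return float(sps.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)
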