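"""Drug-sensitivity inference and in-vitro dose-response analytics.

Transcriptome-based IC50 prediction follows the pharmacogenomic ridge
recipe: train on cell-line expression with observed log-IC50 (missing
entries first filled by k-nearest-neighbor imputation over IC50 profiles),
choose the ridge penalty by 10-fold cross-validation on a log-spaced grid,
then predict log-IC50 for new bulk samples from the shared genes.

In-vitro readouts use the four-parameter logistic (4PL) model

    r(d) = lower + (upper - lower) / (1 + (d / ic50)^hill)

and drug combinations are summarized by the combination index
CI = D1/Dx1 + D2/Dx2 (<1 synergism, =1 additivity, >1 antagonism), where
D are the doses used in combination and Dx the single-agent doses giving
the same effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from wtme.io import ExpressionMatrix

LOW_VARIANCE_SD = 1e-8
DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 25)


# ---------------------------------------------------------------------------
# k-NN IC50 imputation
# ---------------------------------------------------------------------------


def impute_ic50_knn(ic50: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing log-IC50 entries from the k nearest cell lines.

    Distances are Euclidean on per-drug z-scored profiles restricted to the
    drugs both lines observed (scaled by the number of common drugs, so
    lines with few common observations are not artificially close).  k is
    truncated to the number of usable neighbors.
    """
    obs = ic50.notna()
    if (~obs.any(axis=0)).any():
        bad = ic50.columns[~obs.any(axis=0)].tolist()
        raise ValueError(f"drugs with zero observations: {bad}")
    if (~obs.any(axis=1)).any():
        bad = ic50.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"cell lines with zero observations: {bad}")
    if not ic50.isna().any().any():
        return ic50.copy()

    mu = ic50.mean(axis=0)
    sd = ic50.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = ((ic50 - mu) / sd).to_numpy(dtype=float)
    mask = obs.to_numpy()
    filled = ic50.copy()
    n_lines = len(ic50)
    for j, drug in enumerate(ic50.columns):
        missing_rows = np.flatnonzero(~mask[:, j])
        donor_rows = np.flatnonzero(mask[:, j])
        for i in missing_rows:
            common = mask[i] & mask[donor_rows]
            n_common = common.sum(axis=1)
            usable = n_common > 0
            donors = donor_rows[usable]
            if donors.size == 0:
                raise ValueError(
                    f"no usable neighbor for line {ic50.index[i]!r}, drug {drug!r}"
                )
            d2 = np.array(
                [
                    np.mean((z[i, c] - z[r, c]) ** 2)
                    for r, c in zip(donors, common[usable])
                ]
            )
            nearest = donors[np.argsort(d2, kind="stable")[: min(k, donors.size)]]
            filled.iloc[i, j] = float(ic50.iloc[nearest, j].mean())
    return filled


# ---------------------------------------------------------------------------
# Ridge log-IC50 prediction
# ---------------------------------------------------------------------------


@dataclass
class RidgePredictionResult:
    """Predicted log-IC50 per test sample plus the tuning diagnostics."""

    predictions: pd.Series
    drug: str
    alpha: float  # selected ridge penalty
    cv_errors: pd.Series  # mean CV squared error per grid penalty
    n_genes: int
    n_train: int

    def ic50(self) -> pd.Series:
        """Predictions back on the natural (exponentiated) scale."""
        return np.exp(self.predictions)


def predict_ic50_ridge(
    ccl_expression: ExpressionMatrix,
    ic50: pd.DataFrame,
    drug: str,
    test_expression: ExpressionMatrix,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
) -> RidgePredictionResult:
    """Ridge regression of log-IC50 on expression, penalty tuned by CV.

    Genes are intersected between training and test matrices, low-variance
    training genes dropped, and both matrices standardized with the
    *training* mean/sd.  The penalty minimizing mean 10-fold CV squared
    error over the grid is refit on the full training set.
    """
    if drug not in ic50.columns:
        raise ValueError(f"unknown drug {drug!r}")
    y_all = ic50[drug]
    lines = [l for l in ccl_expression.sample_ids if l in y_all.index and pd.notna(y_all[l])]
    if len(lines) < cv_folds:
        raise ValueError(f"need >= {cv_folds} training lines, got {len(lines)}")
    genes = [g for g in ccl_expression.gene_ids if g in test_expression.values.index]
    if not genes:
        raise ValueError("no shared genes between training and test matrices")

    x_train = ccl_expression.values.loc[genes, lines].to_numpy(dtype=float).T
    y = y_all[lines].to_numpy(dtype=float)
    sd = x_train.std(axis=0, ddof=0)
    keep = sd > LOW_VARIANCE_SD
    genes = [g for g, k in zip(genes, keep) if k]
    if not genes:
        raise ValueError("no informative shared genes (all low variance)")
    x_train = x_train[:, keep]
    mu, sd = x_train.mean(axis=0), x_train.std(axis=0, ddof=0)
    x_train = (x_train - mu) / sd
    x_test = test_expression.values.loc[genes].to_numpy(dtype=float).T
    x_test = (x_test - mu) / sd

    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(x_train))
    cv_err = np.zeros(grid.size)
    for gi, lam in enumerate(grid):
        errs = []
        for tr, te in folds:
            model = Ridge(alpha=lam).fit(x_train[tr], y[tr])
            resid = y[te] - model.predict(x_train[te])
            errs.append(float(np.mean(resid**2)))
        cv_err[gi] = float(np.mean(errs))
    best = int(np.argmin(cv_err))
    model = Ridge(alpha=float(grid[best])).fit(x_train, y)
    preds = pd.Series(
        model.predict(x_test), index=test_expression.sample_ids, name=f"log_ic50_{drug}"
    )
    return RidgePredictionResult(
        preds,
        drug,
        float(grid[best]),
        pd.Series(cv_err, index=grid, name="cv_mse"),
        len(genes),
        len(lines),
    )


def compare_group_sensitivity(
    predictions: pd.Series,
    labels: pd.Series | dict,
    lower_group: str = "dWT",
    higher_group: str = "iWT",
) -> tuple[float, float]:
    """One-sided Welch t-test that ``lower_group`` has lower predicted IC50.

    Returns (t, p).  Identical constant groups make the test undefined
    (p = NaN).
    """
    labels = pd.Series(labels)
    a = predictions[[s for s in predictions.index if labels.get(s) == lower_group]]
    b = predictions[[s for s in predictions.index if labels.get(s) == higher_group]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.iloc[0] == b.iloc[0]:
        return 0.0, float("nan")
    res = sps.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Four-parameter logistic dose-response
# ---------------------------------------------------------------------------


def four_param_logistic(d, lower, upper, ic50, hill):
    d = np.asarray(d, dtype=float)
    return lower + (upper - lower) / (1.0 + (d / ic50) ** hill)


@dataclass
class FourPLFit:
    lower: float
    upper: float
    ic50: float
    hill: float
    residual_sd: float
    converged: bool
    n_points: int = 0

    def predict(self, doses) -> np.ndarray:
        return four_param_logistic(doses, self.lower, self.upper, self.ic50, self.hill)


def fit_four_param_logistic(doses, responses) -> FourPLFit:
    """Least-squares 4PL fit with multi-start over the hill-slope sign.

    By construction the fitted curve passes through (lower+upper)/2 at
    d = ic50.  Hopeless (e.g. non-monotone flat) data yields
    ``converged=False`` rather than a silent answer.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.size != r.size:
        raise ValueError("doses and responses differ in length")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if d.size < 5:
        raise ValueError(f"need >= 5 dose points, got {d.size}")

    lo0, hi0 = float(r.min()), float(r.max())
    span = hi0 - lo0
    mid = lo0 + span / 2 if span > 0 else lo0
    # dose nearest the half response as ic50 start; geometric mean fallback
    ic0 = float(d[np.argmin(np.abs(r - mid))])
    if ic0 <= 0:
        ic0 = float(np.exp(np.mean(np.log(d))))

    best = None
    for hill0 in (1.0, -1.0, 3.0, -3.0):
        try:
            popt, _ = optimize.curve_fit(
                four_param_logistic,
                d,
                r,
                p0=[lo0, hi0, ic0, hill0],
                bounds=([-np.inf, -np.inf, 1e-12, -50], [np.inf, np.inf, np.inf, 50]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((r - four_param_logistic(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return FourPLFit(lo0, hi0, ic0, 0.0, float(np.std(r, ddof=0)), False, d.size)
    sse, (lower, upper, ic50, hill) = best
    if upper < lower:  # canonical orientation: flip plateau labels and slope sign
        lower, upper, hill = upper, lower, -hill
    dof = max(d.size - 4, 1)
    residual_sd = float(np.sqrt(sse / dof))
    # no convergence claim unless the curve explains most of the response
    # variance; trendless data must be flagged, not silently summarized
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r_squared = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse < 1e-12 else 0.0)
    converged = r_squared >= 0.5
    return FourPLFit(float(lower), float(upper), float(ic50), float(hill), residual_sd, bool(converged), d.size)


# ---------------------------------------------------------------------------
# Combination index
# ---------------------------------------------------------------------------

ADDITIVITY_TOL = 1e-9


@dataclass
class CombinationResult:
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    call: str  # synergism | additivity | antagonism


def combination_index(d1: float, d2: float, dx1: float, dx2: float) -> CombinationResult:
    """CI = D1/Dx1 + D2/Dx2 with the standard three-way call.

    Additivity is called only at exact equality with 1 (within 1e-9).
    """
    for name, v in (("d1", d1), ("d2", d2), ("dx1", dx1), ("dx2", dx2)):
        if not (v > 0):
            raise ValueError(f"dose {name} must be positive, got {v}")
    ci = d1 / dx1 + d2 / dx2
    if abs(ci - 1.0) <= ADDITIVITY_TOL:
        call = "additivity"
    elif ci < 1.0:
        call = "synergism"
    else:
        call = "antagonism"
    return CombinationResult(d1, d2, dx1, dx2, float(ci), call)
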