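"""Survival analysis: Kaplan-Meier, log-rank, maximally selected rank statistics.

Marker-based stratification uses the maximally selected rank statistic: over
every candidate cutpoint that leaves at least ``min_prop`` of subjects on
each side, the standardized two-group log-rank statistic |Z| is computed for
the induced high/low split, and the maximizing cutpoint is returned.  The
naive log-rank p at the selected cutpoint is anti-conservative (the cutpoint
was chosen to maximize it); an optional permutation-adjusted p accounts for
the selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


def _validate_survival(df: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("survival times must be positive and finite")
    e = df["event"].to_numpy()
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 (censored) or 1 (event)")


@dataclass
class KaplanMeierEstimate:
    """Product-limit survival curve with a risk table."""

    survival: pd.Series  # index time, values S(t); right-continuous steps
    risk_table: pd.DataFrame  # at_risk, events, censored per event time
    median: float

    def at(self, t: float) -> float:
        """S(t) by step lookup (S(0) = 1)."""
        prior = self.survival[self.survival.index <= t]
        return float(prior.iloc[-1]) if len(prior) else 1.0


def kaplan_meier(survival: pd.DataFrame) -> KaplanMeierEstimate:
    """Kaplan-Meier estimate from a table with ``time`` and ``event`` columns."""
    _validate_survival(survival)
    kmf = KaplanMeierFitter()
    kmf.fit(survival["time"], survival["event"])
    curve = kmf.survival_function_["KM_estimate"]
    times = np.sort(survival["time"].unique())
    t = survival["time"].to_numpy(dtype=float)
    e = survival["event"].to_numpy(dtype=int)
    risk = pd.DataFrame(
        {
            "at_risk": [(t >= u).sum() for u in times],
            "events": [((t == u) & (e == 1)).sum() for u in times],
            "censored": [((t == u) & (e == 0)).sum() for u in times],
        },
        index=pd.Index(times, name="time"),
    )
    return KaplanMeierEstimate(curve, risk, float(kmf.median_survival_time_))


@dataclass
class LogrankResult:
    statistic: float  # chi-square
    df: int
    p: float


def logrank_test(survival: pd.DataFrame, group_col: str = "group") -> LogrankResult:
    """Two-sided log-rank test across the groups in ``group_col``."""
    _validate_survival(survival)
    if group_col not in survival.columns:
        raise ValueError(f"missing group column {group_col!r}")
    counts = survival[group_col].value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(
        survival["time"], survival[group_col], survival["event"]
    )
    return LogrankResult(float(res.test_statistic), int(len(counts) - 1), float(res.p_value))


def _logrank_z(time: np.ndarray, event: np.ndarray, in_high: np.ndarray) -> float:
    """Standardized two-group log-rank statistic Z = (O1-E1)/sqrt(V).

    Hypergeometric variance at each distinct event time; returns 0 when the
    variance vanishes (no information).
    """
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = time >= u
        n = at_risk.sum()
        n1 = (at_risk & in_high).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & in_high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


@dataclass
class CutoffResult:
    """Maximally selected rank statistic over marker cutpoints."""

    cutpoint: float
    statistic: float  # max |Z| over admissible cutpoints
    groups: pd.Series  # "high"/"low" per row
    p_naive: float  # chi-square log-rank p at the selected split (anti-conservative)
    p_permutation: float | None = None
    scan: pd.DataFrame | None = None  # cutpoint, |Z| over the whole scan


def optimal_cutoff(
    survival: pd.DataFrame,
    marker_col: str = "marker",
    min_prop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutoffResult:
    """Dichotomize a continuous marker at the log-rank-maximizing cutpoint.

    Candidate cutpoints are the observed marker values; a split uses
    marker > cutpoint as "high" and must leave at least ``min_prop`` of
    subjects on each side.  Ties in the maximal statistic resolve to the
    smaller cutpoint.  With ``n_permutations`` > 0 a permutation-adjusted p
    (marker shuffled, scan repeated) is also returned.
    """
    _validate_survival(survival)
    if marker_col not in survival.columns:
        raise ValueError(f"missing marker column {marker_col!r}")
    n = len(survival)
    if n < 10:
        raise ValueError(f"need >= 10 subjects, got {n}")
    marker = survival[marker_col].to_numpy(dtype=float)
    if np.unique(marker).size < 2:
        raise ValueError("marker is constant")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)

    def scan(mk: np.ndarray) -> tuple[float, float, list[tuple[float, float]]]:
        best_z, best_cut = -np.inf, np.nan
        trace = []
        for cut in np.unique(mk):
            high = mk > cut
            n_high = high.sum()
            if min(n_high, n - n_high) < min_prop * n or n_high in (0, n):
                continue
            z = abs(_logrank_z(time, event, high))
            trace.append((float(cut), z))
            if z > best_z:  # strict: ties keep the smaller cutpoint
                best_z, best_cut = z, float(cut)
        return best_cut, best_z, trace

    cut, stat, trace = scan(marker)
    if not np.isfinite(stat):
        raise ValueError("no admissible cutpoint under min_prop")
    groups = pd.Series(
        np.where(marker > cut, "high", "low"), index=survival.index, name="group"
    )
    p_naive = float(sps.chi2.sf(stat**2, df=1))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            _, z, _ = scan(rng.permutation(marker))
            if z >= stat:
                exceed += 1
        p_perm = (1 + exceed) / (n_permutations + 1)

    scan_df = pd.DataFrame(trace, columns=["cutpoint", "abs_z"])
    return CutoffResult(cut, stat, groups, p_naive, p_perm, scan_df)
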