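"""Copy-number and alteration-level statistics.

Fraction of genome altered (FGA) summarizes a sample's copy-number burden:
with segment means on the log2(copy number / 2) scale, FGA is the number of
profiled bases lying in segments with |log2 ratio| strictly above a
threshold (default 0.2), divided by all profiled bases.  Unprofiled genome
never enters the denominator.

Co-occurrence / mutual-exclusivity of binary alterations is tested per pair
of events with one-sided Fisher exact tests on the 2x2 presence table.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

FGA_THRESHOLD = 0.2

_SIG_TIERS = ((0.01, "**"), (0.05, "*"), (0.1, "."))


def _validate_segments(seg: pd.DataFrame) -> None:
    required = {"sample", "chrom", "start", "end", "log2_ratio"}
    missing = required - set(seg.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(seg["log2_ratio"].to_numpy(dtype=float))):
        raise ValueError("non-finite log2 ratios in segment table")
    bad = seg["end"] < seg["start"]
    if bad.any():
        raise ValueError(f"segments with end < start: {seg.index[bad].tolist()[:5]}")


def fraction_genome_altered(
    segments: pd.DataFrame, threshold: float = FGA_THRESHOLD
) -> pd.Series:
    """Per-sample FGA from 1-based inclusive copy-number segments.

    Strict inequality at the threshold: a segment at exactly |log2 ratio| =
    threshold does not count as altered.  Overlapping segments within a
    sample are an error (base counting would be ambiguous).
    """
    _validate_segments(segments)
    out = {}
    for sample, rows in segments.groupby("sample", sort=True):
        rows = rows.sort_values(["chrom", "start"])
        for chrom, crows in rows.groupby("chrom", sort=False):
            starts = crows["start"].to_numpy()
            ends = crows["end"].to_numpy()
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(
                    f"overlapping segments for sample {sample!r} on {chrom!r}"
                )
        lengths = (rows["end"] - rows["start"] + 1).to_numpy(dtype=float)
        altered = np.abs(rows["log2_ratio"].to_numpy(dtype=float)) > threshold
        out[str(sample)] = float(lengths[altered].sum() / lengths.sum())
    if not out:
        raise ValueError("empty segment table")
    return pd.Series(out, name="fga")


def cooccurrence_tests(alterations: pd.DataFrame) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual-exclusivity of binary events.

    ``alterations`` is samples x events with entries in {0,1}.  For each
    pair the 2x2 table [[both, only A], [only B, neither]] is tested with
    the "greater" tail (co-occurrence) and the "less" tail (exclusivity);
    the reported direction is the smaller of the two one-sided p-values.
    Significance tiers: ``**`` p<0.01, ``*`` p<0.05, ``.`` p<0.1.
    """
    arr = alterations.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("alteration matrix entries must be 0/1")
    if alterations.shape[1] < 2 or alterations.shape[0] < 2:
        raise ValueError("need >= 2 events and >= 2 samples")
    rows = []
    for a, b in combinations(alterations.columns, 2):
        va = alterations[a].to_numpy(dtype=int)
        vb = alterations[b].to_numpy(dtype=int)
        if va.min() == va.max() or vb.min() == vb.max():
            warnings.warn(f"constant event in pair ({a!r}, {b!r}); skipped")
            continue
        both = int(np.sum((va == 1) & (vb == 1)))
        only_a = int(np.sum((va == 1) & (vb == 0)))
        only_b = int(np.sum((va == 0) & (vb == 1)))
        neither = int(np.sum((va == 0) & (vb == 0)))
        table = [[both, only_a], [only_b, neither]]
        p_co = float(sps.fisher_exact(table, alternative="greater")[1])
        p_ex = float(sps.fisher_exact(table, alternative="less")[1])
        if p_co <= p_ex:
            direction, p = "co-occurrence", p_co
        else:
            direction, p = "mutual-exclusivity", p_ex
        tier = ""
        for cutoff, symbol in _SIG_TIERS:
            if p < cutoff:
                tier = symbol
                break
        rows.append(
            {
                "event_a": a,
                "event_b": b,
                "direction": direction,
                "p": p,
                "tier": tier,
                "n_both": both,
                "n_only_a": only_a,
                "n_only_b": only_b,
                "n_neither": neither,
            }
        )
    return pd.DataFrame(rows)
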