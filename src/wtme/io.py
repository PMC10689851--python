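"""Core containers, standard-format readers/writers and preprocessing.

Expression matrices are genes x samples with an explicit scale tag
(``counts``, ``TPM`` or ``log2TPM``) so that each stage can assert the scale
it consumes.  Formats follow the field's text conventions: expression and
survival tables as TSV, gene sets as GMT, copy-number segments as SEG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCALES = ("counts", "TPM", "log2TPM")

TPM_TOTAL = 1e6
#: Consistency constant making the MAD an unbiased sd estimate under normality.
MAD_CONSTANT = 1.4826


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids. Nonnegative,
        finite.
    scale
        One of ``counts``, ``TPM``, ``log2TPM``. On the TPM scale each
        column must sum to 1e6 (relative tolerance 1e-6).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("expression values must be nonnegative")
        if self.scale == "TPM" and arr.size:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                bad = self.values.columns[~np.isclose(sums, TPM_TOTAL, rtol=1e-6)]
                raise ValueError(
                    f"TPM columns must sum to 1e6; offending samples: {list(bad[:5])}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.scale)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 24-cell-type compendium)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def counts_to_tpm(
    counts: ExpressionMatrix, gene_lengths_kb: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million.

    Per sample, each gene's count is divided by its length in kilobases to
    give a length-normalized rate, and rates are rescaled to sum to 1e6.

    Raises
    ------
    ScaleError if the input is not on the counts scale; ValueError naming the
    gene for missing/nonpositive lengths, or naming the sample when all its
    rates are zero (normalization undefined).
    """
    if counts.scale != "counts":
        raise ScaleError(f"expected counts, got {counts.scale}")
    lengths = np.empty(counts.n_genes)
    for i, g in enumerate(counts.gene_ids):
        if g not in gene_lengths_kb:
            raise ValueError(f"no length for gene {g!r}")
        lg = float(gene_lengths_kb[g])
        if not (lg > 0):
            raise ValueError(f"nonpositive length for gene {g!r}: {lg}")
        lengths[i] = lg
    rates = counts.values.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ValueError(f"all-zero samples, TPM undefined: {bad}")
    tpm = TPM_TOTAL * rates / totals
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns),
        "TPM",
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); the +1 pseudocount keeps zero TPM at zero."""
    if m.scale != "TPM":
        raise ScaleError(f"expected TPM, got {m.scale}")
    return ExpressionMatrix(np.log2(m.values + 1.0), "log2TPM")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log_transform`: 2**x - 1, renormalized not at all."""
    if m.scale != "log2TPM":
        raise ScaleError(f"expected log2TPM, got {m.scale}")
    return ExpressionMatrix(np.exp2(m.values) - 1.0, "TPM")


def median_absolute_deviation(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """MAD with the 1.4826 consistency constant (irrelevant to ranking)."""
    med = np.median(values, axis=axis, keepdims=True)
    return MAD_CONSTANT * np.median(np.abs(values - med), axis=axis)


def select_variable_genes(m: ExpressionMatrix, top_fraction: float = 0.1) -> list[str]:
    """Genes whose across-sample MAD lies in the upper decile.

    The count kept is ``ceil(top_fraction * n_genes)``.  Ties at the decile
    boundary are broken by gene-id lexicographic order so the selection is
    deterministic and permutation-invariant to sample order.
    """
    if m.scale != "log2TPM":
        raise ScaleError(f"expected log2TPM, got {m.scale}")
    if m.n_genes < 10:
        raise ValueError(f"need >= 10 genes, got {m.n_genes}")
    mads = median_absolute_deviation(m.values.to_numpy(dtype=float), axis=1)
    if mads.max() == 0:
        raise ValueError("constant matrix: no gene shows variation")
    n_keep = math.ceil(top_fraction * m.n_genes)
    order = sorted(zip(m.gene_ids, mads), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in order[:n_keep]]


def filter_by_purity(
    samples: Sequence[str],
    purity: Mapping[str, float],
    max_purity: float = 0.98,
) -> tuple[list[str], list[str]]:
    """Drop samples whose tumor purity exceeds ``max_purity``.

    Near-pure samples leave too little non-tumor signal for microenvironment
    scoring.  The boundary is strict: purity exactly equal to ``max_purity``
    is retained.  Returns ``(retained, excluded)``.
    """
    retained, excluded = [], []
    for s in samples:
        if s not in purity:
            raise ValueError(f"no purity for sample {s!r}")
        p = float(purity[s])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"purity for {s!r} outside [0,1]: {p}")
        (excluded if p > max_purity else retained).append(s)
    return retained, excluded


# ---------------------------------------------------------------------------
# Readers / writers (round-trip exact for finite values)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Genes-as-rows TSV with a header of sample ids; full float precision."""
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_expression_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "log2_ratio"]


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    """SEG writer; columns sample, chrom, start, end[, num_mark], log2_ratio."""
    df = segments.copy()
    if "num_mark" not in df.columns:
        df["num_mark"] = ""
    df = df[SEG_COLUMNS]
    df.columns = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    mapping = {}
    for want, aliases in {
        "sample": ("id", "sample"),
        "chrom": ("chrom", "chromosome", "chr"),
        "start": ("loc.start", "start"),
        "end": ("loc.end", "end"),
        "log2_ratio": ("seg.mean", "log2_ratio", "seg_mean"),
        "num_mark": ("num.mark", "num_mark"),
    }.items():
        for a in aliases:
            if a in cols:
                mapping[want] = cols[a]
                break
    missing = {"sample", "chrom", "start", "end", "log2_ratio"} - mapping.keys()
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "sample": df[mapping["sample"]].astype(str),
            "chrom": df[mapping["chrom"]].astype(str),
            "start": df[mapping["start"]].astype(int),
            "end": df[mapping["end"]].astype(int),
            "log2_ratio": df[mapping["log2_ratio"]].astype(float),
        }
    )
    if "num_mark" in mapping:
        out["num_mark"] = df[mapping["num_mark"]]
    return out


def write_survival_tsv(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    df["sample"] = df["sample"].astype(str)
    return df


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
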