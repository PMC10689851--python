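"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants two latent microenvironment phenotypes — infiltrated
(immune/stromal signature genes coordinately elevated) and desert (no
elevation) — together with the data the downstream stages consume:

- a TPM expression matrix (generated on the log2 scale, back-transformed
  and column-normalized), with a signature compendium partitioning a block
  of genes into cell-type sets;
- per-sample tumor purity (Beta-distributed, right-skewed by default);
- copy-number segments whose altered fraction tracks a per-phenotype mean
  FGA;
- a binary alteration matrix including a TP53-like event occurring in
  desert samples with configurable sensitivity/specificity;
- exponential survival times with a desert-vs-infiltrated hazard ratio and
  independent censoring.

Each data domain draws from its own RNG stream (spawned from the one seed),
so changing, say, the survival parameters never reshuffles the expression
draw.  Also here: GDSC-style cell-line training data (a linear
expression -> log-IC50 model) and 4PL dose-response readouts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from wtme import io
from wtme.io import ExpressionMatrix, GeneSetCollection

_DOMAINS = ("labels", "expression", "purity", "segments", "alterations", "survival")


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-phenotype cohort.

    Defaults emulate an anaplastic Wilms-tumor cohort at desk scale: 60
    samples, a 24-cell-type compendium of ~15 genes each (~360 signature
    genes), a third of samples desert-like, a 2-fold (log2) coordinated
    elevation of signature genes in infiltrated samples over noise sd 0.5,
    right-skewed Beta(8, 2) purity, a 3x desert-vs-infiltrated hazard
    ratio, and per-phenotype mean FGA of 5% (infiltrated) vs 20% (desert).
    """

    n_samples: int = 60
    n_genes: int = 2000
    n_cell_types: int = 24
    genes_per_signature: int = 15
    phenotype_fraction: float = 1 / 3  # fraction of desert-like samples
    infiltration_effect: float = 2.0  # log2-scale mean shift in infiltrated samples
    #: cell types differ in how strongly infiltration elevates them; each
    #: cell type's shift is infiltration_effect times a fixed multiplier
    #: drawn once per cohort from this range
    cell_type_effect_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.5
    purity_params: tuple[float, float] = (8.0, 2.0)
    hazard_ratio: float = 3.0  # desert vs infiltrated
    censoring_rate: float = 0.3
    fga_means: tuple[float, float] = (0.05, 0.20)  # (infiltrated, desert)
    tp53_sensitivity: float = 0.8  # P(alteration | desert)
    tp53_specificity: float = 1.0  # 1 - P(alteration | infiltrated)
    n_random_events: int = 4
    n_segments: int = 40
    segment_length: int = 5_000_000
    baseline_median_survival: float = 60.0  # months, infiltrated group
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        for name in ("n_genes", "n_cell_types", "genes_per_signature", "n_segments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.genes_per_signature * self.n_cell_types > self.n_genes:
            raise ValueError(
                "genes_per_signature * n_cell_types exceeds n_genes "
                f"({self.genes_per_signature}*{self.n_cell_types} > {self.n_genes})"
            )
        if not (0 < self.phenotype_fraction < 1):
            raise ValueError(
                f"phenotype_fraction must lie in (0,1), got {self.phenotype_fraction}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.hazard_ratio <= 0:
            raise ValueError(f"hazard_ratio must be positive, got {self.hazard_ratio}")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError(f"censoring_rate must lie in [0,1), got {self.censoring_rate}")
        a, b = self.purity_params
        if a <= 0 or b <= 0:
            raise ValueError(f"purity_params must be positive, got {self.purity_params}")
        for v in self.fga_means:
            if not (0 <= v <= 1):
                raise ValueError(f"fga_means must lie in [0,1], got {self.fga_means}")
        for name in ("tp53_sensitivity", "tp53_specificity"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0,1]")


@dataclass
class SyntheticCohort:
    """All tables of one simulated cohort, plus the planted ground truth."""

    expression: ExpressionMatrix  # TPM
    compendium: GeneSetCollection
    purity: pd.Series
    phenotype_truth: pd.Series  # "infiltrated" / "desert"
    segments: pd.DataFrame
    alterations: pd.DataFrame
    survival: pd.DataFrame
    spec: CohortSpec

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    def write(self, out_dir: str | Path) -> None:
        """Write every table in its standard text format, plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression_tsv(self.expression, out / "expression_tpm.tsv")
        io.write_gmt(self.compendium, out / "compendium.gmt")
        io.write_seg(self.segments, out / "segments.seg")
        io.write_survival_tsv(self.survival, out / "survival.tsv")
        io.write_table_tsv(self.purity.to_frame("purity"), out / "purity.tsv")
        io.write_table_tsv(self.alterations, out / "alterations.tsv")
        io.write_table_tsv(
            self.phenotype_truth.to_frame("phenotype"), out / "phenotype_truth.tsv"
        )
        manifest = {"type": "synthetic_cohort", "spec": asdict(self.spec)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_DOMAINS))
    return {name: np.random.default_rng(c) for name, c in zip(_DOMAINS, children)}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic for a fixed seed."""
    spec.validate()
    rngs = _streams(spec.seed)
    n = spec.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]

    # planted phenotypes
    n_desert = max(1, min(n - 1, round(spec.phenotype_fraction * n)))
    desert_idx = np.sort(rngs["labels"].choice(n, size=n_desert, replace=False))
    phenotype = np.array(["infiltrated"] * n, dtype=object)
    phenotype[desert_idx] = "desert"
    truth = pd.Series(phenotype, index=samples, name="phenotype")

    # compendium: a leading block of genes partitioned into cell-type sets
    sets = {}
    for c in range(spec.n_cell_types):
        lo = c * spec.genes_per_signature
        sets[f"cell_type_{c + 1:02d}"] = genes[lo : lo + spec.genes_per_signature]
    compendium = GeneSetCollection(
        sets, {k: "synthetic microenvironment cell-type signature" for k in sets}
    )
    n_sig = spec.n_cell_types * spec.genes_per_signature

    # expression on the log2 scale: gene baselines + planted elevation + noise
    rng = rngs["expression"]
    baseline = rng.uniform(2.0, 8.0, size=spec.n_genes)
    lo, hi = spec.cell_type_effect_range
    cell_type_multiplier = rng.uniform(lo, hi, size=spec.n_cell_types)
    log2 = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    infiltrated_cols = phenotype == "infiltrated"
    sig_effect = spec.infiltration_effect * np.repeat(
        cell_type_multiplier, spec.genes_per_signature
    )
    log2[:n_sig, :][:, infiltrated_cols] += sig_effect[:, None]
    raw = np.exp2(log2)
    tpm = io.TPM_TOTAL * raw / raw.sum(axis=0)
    expression = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples), "TPM")

    # purity
    a, b = spec.purity_params
    purity = pd.Series(rngs["purity"].beta(a, b, size=n), index=samples, name="purity")

    # copy-number segments: equal-length tiles, altered with per-sample prob
    rng = rngs["segments"]
    seg_rows = []
    fga_mean = {"infiltrated": spec.fga_means[0], "desert": spec.fga_means[1]}
    for si, s in enumerate(samples):
        target = float(np.clip(rng.normal(fga_mean[phenotype[si]], 0.03), 0.0, 1.0))
        altered = rng.random(spec.n_segments) < target
        signs = rng.choice([-1.0, 1.0], size=spec.n_segments)
        ratios = np.where(
            altered,
            signs * rng.uniform(0.3, 1.0, size=spec.n_segments),
            rng.normal(0.0, 0.05, size=spec.n_segments).clip(-0.19, 0.19),
        )
        for j in range(spec.n_segments):
            start = 1 + j * spec.segment_length
            seg_rows.append(
                (s, "chr1", start, start + spec.segment_length - 1, float(ratios[j]))
            )
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "log2_ratio"]
    )

    # alterations: TP53-like event tied to the desert phenotype + noise events
    rng = rngs["alterations"]
    tp53 = np.where(
        phenotype == "desert",
        rng.random(n) < spec.tp53_sensitivity,
        rng.random(n) < (1.0 - spec.tp53_specificity),
    ).astype(int)
    alt = {"TP53_like": tp53}
    for e in range(spec.n_random_events):
        prev = rng.uniform(0.1, 0.4)
        alt[f"event_{e + 1:02d}"] = (rng.random(n) < prev).astype(int)
    alterations = pd.DataFrame(alt, index=samples)

    # survival: exponential with hazard_ratio for desert, independent censoring
    rng = rngs["survival"]
    lam0 = np.log(2.0) / spec.baseline_median_survival
    lam = np.where(phenotype == "desert", lam0 * spec.hazard_ratio, lam0)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(n) < spec.censoring_rate
    t_obs = np.where(censored, rng.uniform(0.0, 1.0, size=n) * t_event, t_event)
    t_obs = np.maximum(t_obs, 1e-6)
    survival = pd.DataFrame(
        {"sample": samples, "time": t_obs, "event": (~censored).astype(int)}
    )

    return SyntheticCohort(
        expression, compendium, purity, truth, segments, alterations, survival, spec
    )


# ---------------------------------------------------------------------------
# Cell-line pharmacogenomic training data
# ---------------------------------------------------------------------------


def generate_ccl_training(
    n_lines: int,
    n_genes: int,
    n_drugs: int,
    missing_fraction: float = 0.0,
    noise_sd: float = 0.3,
    n_causal_genes: int = 10,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """GDSC-style training data: log-IC50 linear in expression plus noise.

    Returns ``(expression, ic50, coefficients)``; the coefficient frame is
    gene x drug (sparse: ``n_causal_genes`` nonzero per drug) and includes
    the intercept row ``_intercept``.  A ``missing_fraction`` of IC50
    entries is masked at random (never an entire drug or line).
    """
    if n_lines < 3:
        raise ValueError(f"need >= 3 cell lines, got {n_lines}")
    if not (0 <= missing_fraction < 1):
        raise ValueError(f"missing_fraction must lie in [0,1), got {missing_fraction}")
    rng = np.random.default_rng(seed)
    lines = [f"CCL{i + 1:04d}" for i in range(n_lines)]
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    drugs = [f"drug_{d + 1:02d}" for d in range(n_drugs)]

    x = rng.normal(5.0, 1.0, size=(n_genes, n_lines))
    expression = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=lines), "log2TPM"
    )
    beta = np.zeros((n_genes, n_drugs))
    for d in range(n_drugs):
        causal = rng.choice(n_genes, size=min(n_causal_genes, n_genes), replace=False)
        beta[causal, d] = rng.normal(0.0, 1.0, size=causal.size)
    intercept = rng.normal(2.0, 0.5, size=n_drugs)
    y = x.T @ beta + intercept + rng.normal(0.0, noise_sd, size=(n_lines, n_drugs))
    ic50 = pd.DataFrame(y, index=lines, columns=drugs)

    if missing_fraction > 0:
        mask = rng.random(ic50.shape) < missing_fraction
        # keep every drug and line observable
        for j in range(n_drugs):
            if mask[:, j].all():
                mask[rng.integers(0, n_lines), j] = False
        for i in range(n_lines):
            if mask[i, :].all():
                mask[i, rng.integers(0, n_drugs)] = False
        ic50 = ic50.mask(mask)

    coef = pd.DataFrame(beta, index=genes, columns=drugs)
    coef.loc["_intercept"] = intercept
    return expression, ic50, coef


def generate_dose_response(
    params_4pl: tuple[float, float, float, float],
    doses,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses drawn around a 4PL curve at each dose.

    ``params_4pl`` is (lower, upper, ic50, hill).  Doses must be positive
    and strictly increasing.
    """
    from wtme.pharmaco import four_param_logistic

    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing")
    lower, upper, ic50, hill = params_4pl
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mean = four_param_logistic(d, lower, upper, ic50, hill)
        resp = mean + rng.normal(0.0, noise_sd, size=d.size) if noise_sd > 0 else mean
        for di, ri in zip(d, resp):
            rows.append({"dose": float(di), "response": float(ri), "replicate": rep + 1})
    return pd.DataFrame(rows)
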