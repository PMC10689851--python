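"""End-to-end orchestration of the microenvironment phenotyping workflow.

Stage order mirrors the analysis: simulate (or ingest) a cohort ->
preprocess -> signature scoring (ssGSEA + purity adjustment) -> consensus
subtyping and phenotype naming -> copy-number / alteration statistics ->
differential expression and overlap statistics -> survival contrast ->
drug-sensitivity prediction -> regulons (optional).  Every intermediate is
a text file with a documented schema; the machine-readable report records
parameters, seeds and headline outputs.

One global seed is fanned out per stage by hashing the stage name, so
toggling a stage never reshuffles another stage's draws.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from wtme import io
from wtme.enrichment import EnrichmentParams, adjust_for_purity, ssgsea_score
from wtme.genomics import cooccurrence_tests, fraction_genome_altered
from wtme.pharmaco import compare_group_sensitivity, predict_ic50_ridge
from wtme.regulons import infer_regulons, regulon_activity
from wtme.stats import differential_expression, representation_factor, threshold_de
from wtme.subtyping import ConsensusParams, consensus_cluster, name_phenotypes
from wtme.survival import logrank_test
from wtme.synthetic import CohortSpec, generate_ccl_training, generate_cohort

log = logging.getLogger("wtme.pipeline")

REPORT_SCHEMA_VERSION = 1

_SEED_MOD = 2**31


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed XOR a stage-name hash."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % _SEED_MOD


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "wtme_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    stages: dict = field(default_factory=lambda: {
        "enrichment": True,
        "subtype": True,
        "genomics": True,
        "stats": True,
        "survival": True,
        "pharmaco": True,
        "regulons": False,
    })
    enrichment_params: dict = field(default_factory=dict)  # alpha, normalize
    consensus_params: dict = field(default_factory=lambda: {"k": 2})
    max_purity: float = 0.98
    ccl: dict = field(
        default_factory=lambda: {"n_lines": 120, "n_drugs": 2, "missing_fraction": 0.05,
                                 "noise_sd": 0.3}
    )
    regulon_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        report["failed_stage"] = stage
        _write_report(report, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- simulate -----------------------------------------------------------
    try:
        spec = CohortSpec(**{"seed": stage_seed(config.seed, "simulate"), **config.cohort})
        cohort = generate_cohort(spec)
        cohort.write(out / "cohort")
        report["stages"]["simulate"] = {
            "n_samples": spec.n_samples,
            "n_genes": spec.n_genes,
            "spec": asdict(spec),
        }
        log.info("simulated cohort: %d samples x %d genes", spec.n_samples, spec.n_genes)
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail("simulate", err)

    # --- preprocess ---------------------------------------------------------
    try:
        log_expr = io.log_transform(cohort.expression)
        retained, excluded = io.filter_by_purity(
            cohort.sample_ids, cohort.purity, config.max_purity
        )
        report["stages"]["preprocess"] = {
            "n_retained": len(retained),
            "excluded_samples": excluded,
        }
    except Exception as err:  # noqa: BLE001
        fail("preprocess", err)

    labels = None
    profile_adj = None

    # --- enrichment ---------------------------------------------------------
    if config.stages.get("enrichment", True):
        try:
            params = EnrichmentParams(**config.enrichment_params)
            profile = ssgsea_score(
                log_expr.subset_samples(retained), cohort.compendium, params
            )
            profile_adj = adjust_for_purity(profile, cohort.purity)
            io.write_table_tsv(profile.scores, out / "enrichment_raw.tsv")
            io.write_table_tsv(profile_adj.scores, out / "enrichment_adjusted.tsv")
            report["stages"]["enrichment"] = {
                "n_sets": len(profile.set_names),
                "alpha": params.alpha,
            }
        except Exception as err:  # noqa: BLE001
            fail("enrichment", err)

    # --- subtype ------------------------------------------------------------
    if config.stages.get("subtype", True) and profile_adj is not None:
        try:
            cparams = ConsensusParams(
                **{"seed": stage_seed(config.seed, "subtype"), **config.consensus_params}
            )
            assignment = consensus_cluster(profile_adj.scores, cparams)
            if cparams.k == 2:
                assignment = name_phenotypes(assignment, profile_adj)
            io.write_table_tsv(assignment.consensus_matrix, out / "consensus_matrix.tsv")
            if assignment.phenotype_names is not None:
                labels = assignment.phenotypes
            else:
                labels = assignment.labels.astype(str)
            io.write_table_tsv(labels.to_frame("label"), out / "subtype_labels.tsv")
            truth = cohort.phenotype_truth[labels.index]
            ari = float(adjusted_rand_score(truth, labels))
            report["stages"]["subtype"] = {
                "k": cparams.k,
                "n_perturbations": cparams.n_perturbations,
                "ari_vs_truth": ari,
                "unresolved": assignment.unresolved,
                "counts": labels.value_counts().to_dict(),
            }
            log.info("subtyping ARI vs planted truth: %.3f", ari)
        except Exception as err:  # noqa: BLE001
            fail("subtype", err)

    # --- genomics -----------------------------------------------------------
    if config.stages.get("genomics", True):
        try:
            fga = fraction_genome_altered(cohort.segments)
            io.write_table_tsv(fga.to_frame(), out / "fga.tsv")
            cooc = cooccurrence_tests(cohort.alterations)
            io.write_table_tsv(cooc, out / "cooccurrence.tsv", index=False)
            entry = {"fga_mean": float(fga.mean())}
            if labels is not None:
                entry["fga_by_phenotype"] = {
                    str(g): float(fga[idx.intersection(fga.index)].mean())
                    for g, idx in labels.groupby(labels).groups.items()
                }
            report["stages"]["genomics"] = entry
        except Exception as err:  # noqa: BLE001
            fail("genomics", err)

    # --- stats (differential expression + overlap) --------------------------
    if config.stages.get("stats", True) and labels is not None and set(labels) >= {"iWT", "dWT"}:
        try:
            groups = labels.map({"iWT": 1, "dWT": 2})
            de = differential_expression(log_expr.subset_samples(list(labels.index)), groups)
            io.write_table_tsv(de, out / "differential_expression.tsv")
            up, down = threshold_de(de)
            # microenvironment signature genes are depleted in the desert
            # phenotype, so they should enrich the down-in-dWT set
            sig_genes = {g for genes in cohort.compendium.sets.values() for g in genes}
            overlap = representation_factor(
                m=len(down),
                n=len(sig_genes),
                k=len(down & sig_genes),
                N=cohort.expression.n_genes,
            ) if down else None
            report["stages"]["stats"] = {
                "n_up": len(up),
                "n_down": len(down),
                "rf_down_vs_signature": None if overlap is None else overlap.rf,
                "rf_p": None if overlap is None else overlap.p,
            }
        except Exception as err:  # noqa: BLE001
            fail("stats", err)

    # --- survival ------------------------------------------------------------
    if config.stages.get("survival", True) and labels is not None:
        try:
            surv = cohort.survival.set_index("sample").loc[labels.index].reset_index()
            surv["group"] = labels.to_numpy()
            res = logrank_test(surv)
            med = surv.groupby("group")["time"].median().to_dict()
            report["stages"]["survival"] = {
                "logrank_chi2": res.statistic,
                "logrank_p": res.p,
                "median_time_by_group": {str(k): float(v) for k, v in med.items()},
            }
        except Exception as err:  # noqa: BLE001
            fail("survival", err)

    # --- pharmaco ------------------------------------------------------------
    if config.stages.get("pharmaco", True) and labels is not None and set(labels) >= {"iWT", "dWT"}:
        try:
            ccl_cfg = dict(config.ccl)
            ccl_expr, ic50, _ = generate_ccl_training(
                n_lines=ccl_cfg.get("n_lines", 120),
                n_genes=cohort.expression.n_genes,
                n_drugs=ccl_cfg.get("n_drugs", 2),
                missing_fraction=ccl_cfg.get("missing_fraction", 0.05),
                noise_sd=ccl_cfg.get("noise_sd", 0.3),
                seed=stage_seed(config.seed, "pharmaco"),
            )
            from wtme.pharmaco import impute_ic50_knn

            ic50_full = impute_ic50_knn(ic50)
            drug = ic50_full.columns[0]
            pred = predict_ic50_ridge(
                ccl_expr,
                ic50_full,
                drug,
                io.log_transform(cohort.expression).subset_samples(list(labels.index)),
                seed=stage_seed(config.seed, "pharmaco-cv"),
            )
            io.write_table_tsv(pred.predictions.to_frame(), out / "predicted_ic50.tsv")
            t, p = compare_group_sensitivity(pred.predictions, labels)
            report["stages"]["pharmaco"] = {
                "drug": drug,
                "ridge_alpha": pred.alpha,
                "t_dwt_lower": t,
                "p_dwt_lower": p,
            }
        except Exception as err:  # noqa: BLE001
            fail("pharmaco", err)

    # --- regulons (off by default: the costliest stage) -----------------------
    if config.stages.get("regulons", False):
        try:
            rp = dict(config.regulon_params)
            regulators = rp.pop("regulators", None) or log_expr.gene_ids[:3]
            sub_genes = rp.pop("n_genes", 50)
            sub = log_expr.subset_genes(log_expr.gene_ids[:sub_genes])
            network = infer_regulons(
                sub, [r for r in regulators if r in sub.gene_ids],
                seed=stage_seed(config.seed, "regulons"), **rp,
            )
            io.write_table_tsv(network.to_frame(), out / "regulons.tsv", index=False)
            entry = {"n_edges": len(network.edges)}
            if network.edges:
                activity = regulon_activity(network, sub)
                io.write_table_tsv(activity, out / "regulon_activity.tsv")
                entry["n_regulons_scored"] = activity.shape[1]
            report["stages"]["regulons"] = entry
        except Exception as err:  # noqa: BLE001
            fail("regulons", err)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray, pd.Series)):
            return list(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=default, sort_keys=True))
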