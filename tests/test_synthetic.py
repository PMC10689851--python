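import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from wtme import io
from wtme.enrichment import adjust_for_purity, ssgsea_score
from wtme.genomics import fraction_genome_altered
from wtme.pharmaco import four_param_logistic
from wtme.subtyping import ConsensusParams, consensus_cluster, name_phenotypes
from wtme.survival import logrank_test
from wtme.synthetic import (
    CohortSpec,
    generate_ccl_training,
    generate_cohort,
    generate_dose_response,
)


def recover_phenotypes(cohort, n_perturbations=60, seed=0):
    """Run the scoring + subtyping stages and return named labels."""
    logm = io.log_transform(cohort.expression)
    profile = adjust_for_purity(
        ssgsea_score(logm, cohort.compendium), cohort.purity
    )
    a = consensus_cluster(
        profile.scores, ConsensusParams(k=2, n_perturbations=n_perturbations, seed=seed)
    )
    return name_phenotypes(a, profile)


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        spec = CohortSpec(n_samples=20, n_genes=400, seed=9)
        c1, c2 = generate_cohort(spec), generate_cohort(CohortSpec(n_samples=20, n_genes=400, seed=9))
        pd.testing.assert_frame_equal(c1.expression.values, c2.expression.values)
        pd.testing.assert_series_equal(c1.purity, c2.purity)
        pd.testing.assert_frame_equal(c1.segments, c2.segments)
        pd.testing.assert_frame_equal(c1.survival, c2.survival)
        pd.testing.assert_frame_equal(c1.alterations, c2.alterations)

    def test_structural_invariants(self):
        c = generate_cohort(CohortSpec(n_samples=24, n_genes=600, seed=3))
        # every signature gene in the matrix; TPM columns sum to 1e6
        for genes in c.compendium.sets.values():
            assert set(genes) <= set(c.expression.gene_ids)
        np.testing.assert_allclose(c.expression.values.sum(axis=0), 1e6, rtol=1e-9)
        assert (c.survival["time"] > 0).all()
        assert set(c.survival["event"].unique()) <= {0, 1}
        assert c.alterations.isin([0, 1]).all().all()
        assert ((c.purity >= 0) & (c.purity <= 1)).all()
        assert set(c.phenotype_truth.unique()) == {"infiltrated", "desert"}

    def test_signature_genes_elevated_in_infiltrated(self):
        spec = CohortSpec(n_samples=40, n_genes=800, infiltration_effect=2.0, seed=5)
        c = generate_cohort(spec)
        logm = io.log_transform(c.expression)
        sig = [g for genes in c.compendium.sets.values() for g in genes]
        infiltrated = c.phenotype_truth[c.phenotype_truth == "infiltrated"].index
        desert = c.phenotype_truth[c.phenotype_truth == "desert"].index
        gap = (
            logm.values.loc[sig, infiltrated].mean(axis=1)
            - logm.values.loc[sig, desert].mean(axis=1)
        ).mean()
        assert gap > 0.5  # column renormalization shrinks but keeps the shift

    def test_desert_fga_exceeds_infiltrated(self):
        c = generate_cohort(CohortSpec(n_samples=40, n_genes=400, seed=6))
        fga = fraction_genome_altered(c.segments)
        desert = c.phenotype_truth[c.phenotype_truth == "desert"].index
        infiltrated = c.phenotype_truth[c.phenotype_truth == "infiltrated"].index
        assert fga[desert].mean() > fga[infiltrated].mean() + 0.05

    def test_tp53_event_tracks_desert_truth(self):
        c = generate_cohort(CohortSpec(n_samples=200, n_genes=400, seed=7))
        tp53 = c.alterations["TP53_like"]
        desert = c.phenotype_truth == "desert"
        sens = tp53[desert.to_numpy()].mean()
        fpr = tp53[(~desert).to_numpy()].mean()
        assert 0.6 < sens < 0.95  # around the planted 0.8 sensitivity
        assert fpr == 0.0  # perfect specificity by default

    def test_planted_labels_recoverable(self):
        spec = CohortSpec(n_samples=60, infiltration_effect=2.0, noise_sd=0.5, seed=11)
        c = generate_cohort(spec)
        a = recover_phenotypes(c)
        truth = c.phenotype_truth.map({"desert": "dWT", "infiltrated": "iWT"})
        assert adjusted_rand_score(truth, a.phenotypes) >= 0.9

    def test_null_model_finds_no_signal(self):
        # no planted expression effect and hazard ratio 1: clustering output
        # must carry no survival information beyond chance
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            spec = CohortSpec(
                n_samples=30,
                n_genes=240,
                n_cell_types=8,
                genes_per_signature=10,
                infiltration_effect=0.0,
                hazard_ratio=1.0,
                seed=seed,
            )
            c = generate_cohort(spec)
            a = recover_phenotypes(c, n_perturbations=25, seed=seed)
            surv = c.survival.copy()
            labels = a.phenotypes if a.phenotype_names is not None else a.labels.astype(str)
            surv["group"] = labels.loc[surv["sample"]].to_numpy()
            if logrank_test(surv).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_separation_monotone_in_planted_effect(self):
        gaps = []
        for effect in (0.0, 1.0, 2.0):
            c = generate_cohort(
                CohortSpec(n_samples=30, n_genes=500, infiltration_effect=effect, seed=21)
            )
            logm = io.log_transform(c.expression)
            profile = adjust_for_purity(
                ssgsea_score(logm, c.compendium), c.purity
            )
            means = profile.scores.mean(axis=1)
            inf = c.phenotype_truth == "infiltrated"
            gaps.append(means[inf.to_numpy()].mean() - means[(~inf).to_numpy()].mean())
        assert gaps == sorted(gaps)

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("phenotype_fraction", 1.5, "phenotype_fraction"),
            ("noise_sd", 0.0, "noise_sd"),
            ("hazard_ratio", -1.0, "hazard_ratio"),
            ("censoring_rate", 1.0, "censoring_rate"),
            ("genes_per_signature", 200, "exceeds n_genes"),
        ],
    )
    def test_invalid_spec_names_the_field(self, field, value, match):
        spec = CohortSpec(n_samples=20, n_genes=400)
        setattr(spec, field, value)
        with pytest.raises(ValueError, match=match):
            generate_cohort(spec)

    def test_rng_streams_are_independent_per_domain(self):
        base = CohortSpec(n_samples=20, n_genes=400, seed=13)
        alt = CohortSpec(n_samples=20, n_genes=400, seed=13, hazard_ratio=5.0)
        c1, c2 = generate_cohort(base), generate_cohort(alt)
        # changing a survival parameter must not reshuffle expression draws
        pd.testing.assert_frame_equal(c1.expression.values, c2.expression.values)
        pd.testing.assert_frame_equal(c1.segments, c2.segments)

    def test_written_cohort_round_trips(self, tmp_path):
        c = generate_cohort(CohortSpec(n_samples=10, n_genes=400, seed=2))
        c.write(tmp_path)
        back = io.read_expression_tsv(tmp_path / "expression_tpm.tsv", "TPM")
        pd.testing.assert_frame_equal(back.values, c.expression.values)
        assert io.read_gmt(tmp_path / "compendium.gmt").sets == c.compendium.sets
        seg = io.read_seg(tmp_path / "segments.seg")
        pd.testing.assert_frame_equal(
            seg[["sample", "chrom", "start", "end", "log2_ratio"]],
            c.segments[["sample", "chrom", "start", "end", "log2_ratio"]],
        )


class TestGenerateCclTraining:
    def test_no_missing_when_fraction_zero(self):
        _, ic50, _ = generate_ccl_training(10, 20, 3, missing_fraction=0.0, seed=0)
        assert not ic50.isna().any().any()

    def test_missing_fraction_roughly_respected(self):
        _, ic50, _ = generate_ccl_training(100, 20, 5, missing_fraction=0.2, seed=1)
        frac = ic50.isna().to_numpy().mean()
        assert 0.12 < frac < 0.28
        assert ic50.notna().any(axis=0).all() and ic50.notna().any(axis=1).all()

    def test_log_ic50_is_linear_in_expression(self):
        expr, ic50, coef = generate_ccl_training(20, 15, 2, 0.0, noise_sd=0.0, seed=2)
        x = expr.values.to_numpy().T
        recon = x @ coef.iloc[:-1].to_numpy() + coef.loc["_intercept"].to_numpy()
        np.testing.assert_allclose(ic50.to_numpy(), recon, rtol=1e-10)

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            generate_ccl_training(2, 5, 1)


class TestGenerateDoseResponse:
    def test_noiseless_midpoint_at_ic50(self):
        table = generate_dose_response((0.2, 0.8, 1.0, 2.0), [0.25, 0.5, 1.0, 2.0], 0.0)
        at_ic50 = table.loc[table["dose"] == 1.0, "response"].iloc[0]
        assert at_ic50 == pytest.approx(0.5)

    def test_zero_hill_is_flat_at_midpoint(self):
        table = generate_dose_response((0.0, 1.0, 1.0, 0.0), [0.1, 1.0, 10.0], 0.0)
        np.testing.assert_allclose(table["response"], 0.5)

    def test_noiseless_curve_matches_model(self):
        doses = np.logspace(-1, 1, 6)
        table = generate_dose_response((0.1, 0.9, 2.0, 1.5), doses, 0.0)
        np.testing.assert_allclose(
            table["response"], four_param_logistic(doses, 0.1, 0.9, 2.0, 1.5)
        )

    @pytest.mark.parametrize(
        "doses,match",
        [([0.0, 1.0], "positive"), ([2.0, 1.0], "increasing")],
    )
    def test_invalid_doses_rejected(self, doses, match):
        with pytest.raises(ValueError, match=match):
            generate_dose_response((0, 1, 1, 1), doses)
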