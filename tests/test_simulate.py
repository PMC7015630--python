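"""The synthetic GWAS generator: construction identities, determinism, and
statistical sanity of the generated studies."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from mrkit.instruments import build_instruments, harmonise
from mrkit.score import compute_grs, grs_r2, observational_or
from mrkit.simulate import (
    ScenarioConfig,
    gen_cohort,
    gen_exposure_gwas,
    gen_ld_reference,
    gen_outcome_gwas,
    gen_study_outcomes,
    run_mr_replicates,
    scenario_preset,
    simulate_study,
)


def _r2_of(truth, idx=None):
    het = 2 * truth.eaf * (1 - truth.eaf)
    if idx is None:
        return float(np.sum(het * truth.beta_x_true**2))
    return float(np.sum(het[idx] * truth.beta_x_true[idx] ** 2))


class TestExposureGeneration:
    def test_r2_construction_identity(self):
        cfg = ScenarioConfig(n_variants=212, r2_target=0.127, seed=11)
        _, truth = gen_exposure_gwas(cfg)
        assert _r2_of(truth) == pytest.approx(0.127, abs=1e-10)

    def test_subset_r2_construction_identity(self):
        cfg = scenario_preset("paper_shape", seed=11)
        _, truth = gen_exposure_gwas(cfg)
        sub = [truth.index(r) for r in truth.subset_rsids]
        assert _r2_of(truth, sub) == pytest.approx(0.017, abs=1e-10)
        assert _r2_of(truth) == pytest.approx(0.127, abs=1e-10)
        assert set(truth.subset_genes.values()) == {"HFE", "TMPRSS6", "TFRC", "TFR2"}

    def test_large_sample_observed_converges_to_truth(self):
        cfg = ScenarioConfig(n_variants=50, n_exposure=10**9, seed=3)
        _, truth = gen_exposure_gwas(cfg)
        assert np.allclose(truth.beta_x_obs, truth.beta_x_true, atol=1e-3)

    def test_determinism_under_fixed_seed(self):
        cfg = ScenarioConfig(n_variants=30, seed=9)
        ss1, t1 = gen_exposure_gwas(cfg)
        ss2, t2 = gen_exposure_gwas(cfg)
        assert ss1.records == ss2.records
        assert np.array_equal(t1.beta_x_true, t2.beta_x_true)

    def test_standardised_residuals_are_normal(self):
        # Kolmogorov-Smirnov on (observed - true)/se at n=1000, fixed seed
        cfg = ScenarioConfig(n_variants=1000, r2_target=0.2, seed=4)
        _, truth = gen_exposure_gwas(cfg)
        z = (truth.beta_x_obs - truth.beta_x_true) / truth.se_x
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_effects_oriented_to_increasing_allele(self):
        _, truth = gen_exposure_gwas(ScenarioConfig(n_variants=40, seed=5))
        assert np.all(truth.beta_x_true > 0)


class TestOutcomeGeneration:
    def test_null_outcome_centred_at_zero(self):
        cfg = ScenarioConfig(n_variants=100, causal_log_or=0.0, seed=21)
        _, truth = gen_exposure_gwas(cfg)
        out = gen_outcome_gwas(cfg, truth)
        assert np.all(truth.beta_y_true == 0.0)
        instr, _ = harmonise(gen_exposure_gwas(cfg)[0].records, out)
        by = np.array([i.beta_outcome for i in instr])
        sy = np.array([i.se_outcome for i in instr])
        pooled_se = 1 / math.sqrt(np.sum(1 / sy**2))
        assert abs(np.average(by, weights=1 / sy**2)) <= 3 * pooled_se

    def test_causal_slope_construction_identity(self):
        cfg = ScenarioConfig(n_variants=60, causal_log_or=0.2, seed=22)
        _, truth = gen_exposure_gwas(cfg)
        # exact proportionality without pleiotropy
        assert np.allclose(truth.beta_y_true, 0.2 * truth.beta_x_true, atol=1e-15)

    def test_two_sample_noise_independence(self):
        # exposure and outcome observation errors must be uncorrelated
        cfg = ScenarioConfig(n_variants=2000, causal_log_or=0.0, seed=23)
        _, truth = gen_exposure_gwas(cfg)
        out = gen_outcome_gwas(cfg, truth)
        ex_err = (truth.beta_x_obs - truth.beta_x_true) / truth.se_x
        by = np.array([out.get(r).beta for r in truth.rsids])
        se_y = np.array([out.get(r).se for r in truth.rsids])
        swap = np.where(truth.swap_mask, -1.0, 1.0)
        out_err = swap * by / se_y
        r = np.corrcoef(ex_err, out_err)[0, 1]
        assert abs(r) < 3 / math.sqrt(len(ex_err))

    def test_directional_pleiotropy_one_signed(self):
        cfg = scenario_preset("directional_pleiotropy", seed=8)
        _, truth = gen_exposure_gwas(cfg)
        assert np.all(truth.direct_effects >= 0.0)
        n_invalid = int(np.sum(truth.direct_effects > 0))
        assert n_invalid == round(0.3 * cfg.n_variants)

    def test_per_study_split_matches_totals(self):
        cfg = scenario_preset("four_study", seed=2)
        _, truth = gen_exposure_gwas(cfg)
        studies = gen_study_outcomes(cfg, truth)
        assert set(studies) == {"NIHRBR", "PAHB", "PHAAR", "BHFPAH"}
        assert sum(s.n_cases for s in studies.values()) == 2085
        assert sum(s.n_total for s in studies.values()) == 11_744


class TestLDReferenceGeneration:
    def test_singleton_blocks_are_empty(self):
        cfg = ScenarioConfig(n_variants=5, ld_blocks=((1, 0.9),) * 5, seed=1)
        _, truth = gen_exposure_gwas(cfg)
        ref = gen_ld_reference(cfg, truth)
        assert ref.to_pairs() == []

    def test_block_of_three_mutually_linked(self):
        cfg = ScenarioConfig(n_variants=6, ld_blocks=((3, 0.9),), seed=1)
        _, truth = gen_exposure_gwas(cfg)
        ref = gen_ld_reference(cfg, truth)
        a, b, c = truth.rsids[:3]
        for x, y in ((a, b), (a, c), (b, c)):
            assert ref.r2(x, y) == 0.9
            assert ref.r2(y, x) == 0.9  # symmetric by construction
        assert ref.r2(a, truth.rsids[3]) == 0.0


class TestCohortGeneration:
    def test_zero_noise_limit_gives_r2_one(self):
        cfg = ScenarioConfig(n_variants=20, cohort_n=500, grs_r2_target=1.0, seed=6)
        _, truth = gen_exposure_gwas(cfg)
        cohort = gen_cohort(cfg, truth)
        scores = compute_grs(cohort, dict(zip(truth.rsids, truth.beta_x_obs)))
        assert grs_r2(cohort, scores, seed=1, n_boot=100).r2 == pytest.approx(1.0)

    def test_null_case_model_covers_or_one(self):
        cfg = ScenarioConfig(
            n_variants=10, cohort_n=4000, cohort_case_fraction=0.2,
            obs_log_or_per_sd=0.0, seed=6,
        )
        _, truth = gen_exposure_gwas(cfg)
        cohort = gen_cohort(cfg, truth)
        _, lo, hi = observational_or(cohort)
        assert lo < 1.0 < hi

    def test_case_fraction_targeted(self):
        cfg = ScenarioConfig(n_variants=10, cohort_n=20_000,
                             cohort_case_fraction=0.15, seed=7)
        _, truth = gen_exposure_gwas(cfg)
        cohort = gen_cohort(cfg, truth)
        frac = cohort.data["is_case"].mean()
        assert frac == pytest.approx(0.15, abs=3 * math.sqrt(0.15 * 0.85 / 20_000))


class TestPresets:
    def test_preset_determinism(self):
        assert scenario_preset("paper_shape", seed=4) == scenario_preset("paper_shape", seed=4)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_preset("nope")

    def test_null_preset_is_null(self):
        assert scenario_preset("null", seed=0).causal_log_or == 0.0

    def test_paper_shape_audit_counts(self):
        # construction identity of the instrument bookkeeping:
        # 212 significant and independent, 13 palindromic dropped,
        # 32 absent of which 12 proxy-recovered -> 179 final
        study = simulate_study(scenario_preset("paper_shape", seed=7), with_cohort=False)
        _, audit = build_instruments(study.exposure, study.outcome, study.ld)
        assert audit.n_significant == 212
        assert audit.n_independent == 212
        assert audit.n_palindromic_dropped == 13
        assert audit.n_proxied == 12
        assert audit.n_unmatched == 20
        assert audit.n_final == 179
        audit.check()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_variants=0)
        with pytest.raises(ValueError):
            ScenarioConfig(subset_size=3, subset_r2=None)
        with pytest.raises(ValueError):
            ScenarioConfig(n_missing_outcome=1, n_proxy_recoverable=2)


class TestReplicateRunner:
    def test_replicates_are_deterministic(self):
        cfg = ScenarioConfig(n_variants=20, seed=0)
        a = run_mr_replicates(cfg, 5, seed=31)
        b = run_mr_replicates(cfg, 5, seed=31)
        assert a.equals(b)

    def test_causal_recovery_within_three_mc_ses(self):
        # mean IVW estimate over replicates near the true causal log-OR
        b_true = math.log(1.5)
        cfg = ScenarioConfig(n_variants=150, r2_target=0.12,
                             causal_log_or=b_true, seed=0)
        reps = run_mr_replicates(cfg, 200, seed=19)
        mc_se = reps["beta_ivw"].std(ddof=1) / math.sqrt(len(reps))
        assert abs(reps["beta_ivw"].mean() - b_true) <= 3 * mc_se

    def test_ci_coverage_near_nominal(self):
        b_true = math.log(1.5)
        cfg = ScenarioConfig(n_variants=150, r2_target=0.12,
                             causal_log_or=b_true, seed=0)
        reps = run_mr_replicates(cfg, 200, seed=20)
        z = 1.959963984540054
        covered = (
            (reps["beta_ivw"] - z * reps["se_ivw"] <= b_true)
            & (b_true <= reps["beta_ivw"] + z * reps["se_ivw"])
        ).mean()
        assert 0.92 <= covered <= 0.98
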