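import json

import numpy as np
import pytest
from scipy.special import expit

from wprskit.datatypes import MISSING
from wprskit.metrics import auroc
from wprskit.qc import call_rate, hwe_exact_p
from wprskit.scoring import weighted_prs
from wprskit.simulate import (
    DEFAULT_COVARIATES,
    SimulationConfig,
    analytic_auroc,
    make_fixture_bundle,
    simulate_case_control,
    simulate_genotypes,
    simulate_normal_scores,
)

from conftest import weights_for

ZERO_COVARIATES = {k: (p, 0.0) for k, (p, _) in DEFAULT_COVARIATES.items()}


def small_cfg(seed, **kw):
    base = dict(seed=seed, n_cases_a=60, n_cases_b=50, n_controls=80, missing_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenotypes:
    def test_no_missing_gives_full_call_rate(self):
        cfg = SimulationConfig(seed=1, missing_rate=0.0)
        gm = simulate_genotypes(cfg, n=100)
        assert all(call_rate(gm, v) == 1.0 for v in gm.vids)

    def test_missing_rate_injected(self):
        cfg = SimulationConfig(seed=1, missing_rate=0.1)
        gm = simulate_genotypes(cfg, n=500)
        frac = (gm.dosages == MISSING).mean()
        assert 0.08 < frac < 0.12

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_genotypes(cfg, n=50)
        b = simulate_genotypes(cfg, n=50)
        assert a == b

    def test_hardy_weinberg_holds_under_the_null(self):
        cfg = SimulationConfig(seed=5, missing_rate=0.0)
        gm = simulate_genotypes(cfg, n=10_000)
        passing = 0
        for v in gm.vids:
            col = gm.column(v)
            p = hwe_exact_p(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            passing += p >= 1e-6
        assert passing >= 0.99 * gm.n_variants


class TestSimulateCaseControl:
    def test_quota_sizes_and_labels(self):
        study = simulate_case_control(small_cfg(2))
        counts = study.cohort.groupby(["cohort", "label"]).size()
        assert counts[("A", "case")] == 60
        assert counts[("B", "case")] == 50
        assert counts[("control", "control")] == 80

    def test_deterministic_given_seed(self):
        a = simulate_case_control(small_cfg(9))
        b = simulate_case_control(small_cfg(9))
        assert a.genotypes == b.genotypes
        assert a.cohort.equals(b.cohort)

    def test_intercept_bisection_hits_target_fraction(self):
        from wprskit.simulate import _draw_covariates, _linear_predictor

        cfg = small_cfg(3, population_case_fraction=0.2)
        study = simulate_case_control(cfg)
        rng = np.random.default_rng(123)
        G = rng.binomial(2, study.mafs, size=(30_000, cfg.n_variants)).astype(float)
        cov = _draw_covariates(cfg, 30_000, rng)
        lp = _linear_predictor(cfg, G, cov, study.true_beta_a)
        # realised population case probability close to the configured target
        assert abs(expit(study.intercepts[0] + lp).mean() - 0.2) < 0.02

    def test_null_panel_gives_chance_auroc(self):
        cfg = SimulationConfig(
            seed=11, true_weights=np.zeros(31), covariates=ZERO_COVARIATES,
            age_effect=0.0, n_cases_a=600, n_cases_b=600, n_controls=800,
            missing_rate=0.0,
        )
        study = simulate_case_control(cfg)
        # score with an arbitrary non-zero panel: labels are independent of
        # genotype, so discrimination must sit at chance
        rng = np.random.default_rng(0)
        wt = weights_for(study.genotypes, rng=rng)
        scores = weighted_prs(study.genotypes, wt)
        merged = scores.merge(study.cohort, on="sample_id")
        sub = merged[(merged["cohort"] == "A") | (merged["label"] == "control")]
        a = auroc((sub["label"] == "case").to_numpy(int), sub["wprs"].to_numpy())
        assert 0.45 <= a.auroc <= 0.55

    def test_case_enrichment_with_real_effects(self):
        study = simulate_case_control(small_cfg(4))
        scores = weighted_prs(study.genotypes, study.weights)
        merged = scores.merge(study.cohort, on="sample_id")
        sub = merged[(merged["cohort"] == "A") | (merged["label"] == "control")]
        a = auroc((sub["label"] == "case").to_numpy(int), sub["wprs"].to_numpy())
        assert a.auroc > 0.7

    def test_impossible_quota_raises(self):
        cfg = small_cfg(6, population_case_fraction=0.001, max_draw_factor=2)
        with pytest.raises(RuntimeError, match="quota"):
            simulate_case_control(cfg)


class TestCrossDiseaseStructure:
    def _cross_auroc(self, shared, seed):
        cfg = SimulationConfig(
            seed=seed, shared_effect_fraction=shared, missing_rate=0.0,
            n_cases_a=250, n_cases_b=222, n_controls=296,
        )
        study = simulate_case_control(cfg)
        scores = weighted_prs(study.genotypes, study.weights)
        merged = scores.merge(study.cohort, on="sample_id")
        out = {}
        for tag in ("A", "B"):
            sub = merged[(merged["cohort"] == tag) | (merged["label"] == "control")]
            out[tag] = auroc((sub["label"] == "case").to_numpy(int), sub["wprs"].to_numpy()).auroc
        return out

    def test_fully_shared_panel_transfers(self):
        res = self._cross_auroc(1.0, seed=21)
        assert abs(res["A"] - res["B"]) < 0.08

    def test_unshared_panel_does_not_transfer(self):
        res = self._cross_auroc(0.0, seed=22)
        assert abs(res["B"] - 0.5) < 0.08
        assert res["A"] > 0.75

    def test_discrimination_monotone_in_effect_size(self):
        def median_auc(scale):
            aucs = []
            for rep in range(8):
                cfg = SimulationConfig(
                    seed=1000 + rep, true_weights=np.full(31, scale),
                    n_cases_a=100, n_cases_b=30, n_controls=100, missing_rate=0.0,
                )
                study = simulate_case_control(cfg)
                scores = weighted_prs(study.genotypes, study.weights)
                merged = scores.merge(study.cohort, on="sample_id")
                sub = merged[(merged["cohort"] == "A") | (merged["label"] == "control")]
                aucs.append(
                    auroc((sub["label"] == "case").to_numpy(int), sub["wprs"].to_numpy()).auroc
                )
            return np.median(aucs)

        assert median_auc(0.6) >= median_auc(0.1)


class TestLiabilityNormalOption:
    def test_matches_analytic_auroc(self):
        from scipy.stats import norm

        target = 0.95
        delta = np.sqrt(2.0) * norm.ppf(target)
        labels, scores = simulate_normal_scores(delta, 2000, 2000, seed=77)
        emp = auroc(labels, scores).auroc
        assert emp == pytest.approx(analytic_auroc(delta), abs=0.02)
        assert analytic_auroc(delta) == pytest.approx(target, abs=1e-12)


class TestFixtureBundle:
    def test_bundle_reproducible_byte_for_byte(self, tmp_path):
        cfg = small_cfg(33, missing_rate=0.05)
        m1 = make_fixture_bundle(cfg, tmp_path / "a")
        m2 = make_fixture_bundle(cfg, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_pipeline_matches_bundled_expected_scores(self, tmp_path):
        import pandas as pd

        from wprskit.genotype_io import read_plink, read_weight_table

        cfg = small_cfg(34, missing_rate=0.1)
        make_fixture_bundle(cfg, tmp_path / "fix")
        gm = read_plink(tmp_path / "fix" / "study")
        wt = read_weight_table(tmp_path / "fix" / "weights.tsv")
        expected = pd.read_csv(tmp_path / "fix" / "expected_scores.tsv", sep="\t")
        got = weighted_prs(gm, wt, mode="average")
        np.testing.assert_allclose(
            got["wprs"].to_numpy(), expected["wprs_average"].to_numpy(), atol=1e-10
        )
        np.testing.assert_array_equal(
            got["risk_allele_count"].to_numpy(), expected["risk_allele_count"].to_numpy()
        )

    def test_missing_cells_accounted_for(self, tmp_path):
        cfg = small_cfg(35, missing_rate=0.2)
        make_fixture_bundle(cfg, tmp_path / "miss")
        from wprskit.genotype_io import read_plink, read_weight_table

        gm = read_plink(tmp_path / "miss" / "study")
        injected = int((gm.dosages == MISSING).sum())
        got = weighted_prs(gm, read_weight_table(tmp_path / "miss" / "weights.tsv"))
        assert int(got["n_imputed_cells"].sum()) == injected
        manifest = json.loads((tmp_path / "miss" / "manifest.json").read_text())
        assert manifest["n_variants"] == 31
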