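"""Association engine and screening-stage contracts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from omicloops import (
    bh_adjust,
    collapse_correlated_snps,
    cross_omic_metabolite_tests,
    differential_abundance,
    fit_lm,
    metabolite_bmi_screen,
    persistent_bmi_scan,
    targeted_mgwas,
)
from omicloops.associations import DegenerateFitError, find_persistent_run, tss_log
from omicloops.features import compute_features
from omicloops.model import MultiOmicsIntegration

from conftest import make_genotype, make_metabolome, make_phenotypes


class TestFitLm:
    def test_exact_linear_relation(self):
        x = np.arange(20, dtype=float)
        fit = fit_lm(2.0 * x, x)
        assert fit.beta == pytest.approx(2.0, abs=1e-12)
        assert fit.p < 1e-200

    def test_orthogonal_exposure_gives_zero_slope(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        y = np.tile([1.0, -1.0], 10)  # orthogonal to x and to the intercept
        assert abs(np.dot(x, y)) < 1e-12
        fit = fit_lm(y, x)
        assert abs(fit.beta) < 1e-10

    def test_matches_closed_form_normal_equations_and_statsmodels(self):
        rng = np.random.default_rng(12)
        n = 50
        x = rng.normal(size=n)
        cov = pd.DataFrame({"race": rng.choice(["a", "b", "c"], n),
                            "sex": rng.choice(["f", "m"], n)})
        y = 0.7 * x + rng.normal(size=n)
        fit = fit_lm(y, x, cov)

        # independent closed-form oracle: (X'X)^-1 X'y with hand-built dummies
        D = pd.get_dummies(cov, drop_first=True, dtype=float).to_numpy()
        X = np.column_stack([np.ones(n), D, x])
        beta_hat = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta_hat
        s2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        p = 2 * stats.t.sf(abs(beta_hat[-1] / se[-1]), n - X.shape[1])
        assert fit.beta == pytest.approx(beta_hat[-1], abs=1e-10)
        assert fit.se == pytest.approx(se[-1], abs=1e-10)
        assert fit.p == pytest.approx(p, abs=1e-10)

        sm_fit = sm.OLS(y, X).fit()
        assert fit.beta == pytest.approx(sm_fit.params[-1], abs=1e-10)
        assert fit.p == pytest.approx(sm_fit.pvalues[-1], abs=1e-10)

    def test_listwise_deletion_reported(self):
        x = np.arange(30, dtype=float)
        y = 2 * x
        y[3] = np.nan
        x[7] = np.nan
        assert fit_lm(y, x).n_used == 28

    def test_constant_exposure_is_degenerate(self):
        with pytest.raises(DegenerateFitError, match="constant"):
            fit_lm(np.random.default_rng(0).normal(size=20), np.ones(20))

    def test_collinear_covariate_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        cov = pd.DataFrame({"a": rng.normal(size=30)})
        cov["b"] = 2 * cov["a"]  # exactly collinear
        with caplog.at_level("WARNING", logger="omicloops"):
            fit = fit_lm(x + rng.normal(size=30), x, cov)
        assert fit.dropped == ["b"]


class TestBhAdjust:
    def test_worked_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCollapseCorrelatedSnps:
    def test_duplicated_column_grouped(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.3, 200)
        gt = make_genotype(np.column_stack([a, a, rng.binomial(2, 0.3, 200)]),
                           snp_ids=["rs1", "rs2", "rs3"])
        groups = collapse_correlated_snps(gt, 0.9)
        assert ["rs1", "rs2"] in groups.groups
        assert groups.partners("rs1") == {"rs2"}
        assert groups.partners("rs3") == set()

    def test_independent_snps_all_singletons(self, null_cohort):
        groups = collapse_correlated_snps(null_cohort.genotype, 0.9)
        pair = null_cohort.config.ld_pairs[0]
        for g in groups.groups:
            if len(g) > 1:
                assert sorted(g) == sorted([pair.snp_a, pair.snp_b])

    def test_single_linkage_chains_transitively(self):
        rng = np.random.default_rng(42)
        n = 8000
        a = rng.binomial(2, 0.3, n).astype(float)
        b, c = a.copy(), None
        flip = rng.random(n) < 0.05
        b[flip] = rng.binomial(2, 0.3, int(flip.sum()))
        c = b.copy()
        flip = rng.random(n) < 0.05
        c[flip] = rng.binomial(2, 0.3, int(flip.sum()))
        gt = make_genotype(np.column_stack([a, b, c]), snp_ids=["A", "B", "C"])
        corr = gt.mac.corr().abs()
        # construction check: A~B and B~C above threshold, A~C below
        assert corr.loc["A", "B"] >= 0.92 and corr.loc["B", "C"] >= 0.92
        assert corr.loc["A", "C"] < 0.92
        groups = collapse_correlated_snps(gt, 0.92)
        assert groups.groups == [["A", "B", "C"]]


class TestTargetedMgwas:
    def test_bonferroni_threshold_counts_tests_performed(self, null_cohort):
        features = {age: compute_features(mb, k=2)
                    for age, mb in null_cohort.microbiome.items()}
        res = targeted_mgwas(null_cohort.genotype, features,
                             null_cohort.phenotypes.covariates)
        m = res.extra["m"]
        assert m == len(res.table)
        assert m == 30 * 4 * 4  # SNPs x features x ages, none skipped
        assert res.extra["bonferroni_threshold"] == pytest.approx(0.05 / m)

    def test_null_cohort_has_no_bonferroni_hits(self, null_cohort):
        features = {age: compute_features(mb, k=2)
                    for age, mb in null_cohort.microbiome.items()}
        res = targeted_mgwas(null_cohort.genotype, features,
                             null_cohort.phenotypes.covariates)
        assert sum(e.tier == "significant" for e in res.edges) == 0


class TestPersistence:
    def test_worked_run_example(self):
        p = [0.2, 0.005, 0.004, 0.008, 0.003, 0.009, 0.5]
        betas = [1.0] * 7
        assert find_persistent_run(p, betas, 0.01, 5) == (1, 5)
        assert find_persistent_run(p, betas, 0.01, 6) is None

    def test_sign_flip_breaks_run(self):
        p = [0.005, 0.004, 0.008, 0.003, 0.009]
        betas = [1.0, 1.0, -1.0, 1.0, 1.0]
        assert find_persistent_run(p, betas, 0.01, 5) is None
        assert find_persistent_run(p, betas, 0.01, 5,
                                   require_consistent_sign=False) == (0, 4)

    def test_planted_snp_bmi_association_is_persistent(self, loop_cohort):
        snp = next(e.source[1] for e in loop_cohort.truth
                   if e.source[0] == "snp" and e.target[0] == "bmi")
        res = persistent_bmi_scan(loop_cohort.genotype, loop_cohort.phenotypes)
        hits = [e for e in res.edges if e.node_a == snp]
        assert hits, "planted persistent association not found"
        assert all(e.sign == 1 for e in hits)
        lo, hi = hits[0].age
        assert hi - lo >= 4  # at least 5 consecutive yearly ages

    def test_too_few_ages_yields_empty_result(self, loop_cohort):
        ph = loop_cohort.phenotypes
        short = make_phenotypes(ph.bmi_percentile.iloc[:, :3])
        res = persistent_bmi_scan(loop_cohort.genotype, short)
        assert res.edges == []


class TestDifferentialAbundance:
    def test_low_prevalence_genus_excluded_from_tests_and_bh_family(self):
        rng = np.random.default_rng(0)
        n = 200
        counts = pd.DataFrame(
            rng.integers(5, 50, size=(n, 3)),
            index=[f"S{i:03d}" for i in range(n)], columns=["g1", "g2", "rare"],
        )
        counts["rare"] = 0
        counts.loc[counts.index[:10], "rare"] = 5  # 5% prevalence
        from omicloops.tables import MicrobiomeCounts

        mb = MicrobiomeCounts(counts, age_years=3.0)
        gt = make_genotype(rng.binomial(2, 0.3, size=(n, 1)), snp_ids=["rs1"],
                           sample_ids=list(counts.index))
        ph = make_phenotypes(pd.DataFrame({3.0: rng.uniform(0, 100, n)},
                                          index=counts.index))
        res = differential_abundance(mb, gt, ["rs1"], ph.covariates, prevalence_min=0.1)
        assert "rare" not in set(res.table["genus"])
        assert len(res.table) == 2

    def test_planted_snp_genus_effect_detected_with_sign(self):
        from omicloops import CohortConfig, PlantedEffect, default_config, simulate_cohort

        cfg = default_config(n_samples=600, n_snps=6, n_genera=20, n_metabolites=5,
                             sequencing_depth=2000, seed=21)
        snp = cfg.snp_panel[3].snp_id
        genus = cfg._genus_ids()[4]
        eff = PlantedEffect(("snp", snp), ("genus", genus), 0.8)
        cfg = CohortConfig(**{**cfg.__dict__, "planted_effects": [eff]})
        cohort = simulate_cohort(cfg)
        res = differential_abundance(cohort.microbiome[3.0], cohort.genotype, [snp],
                                     cohort.phenotypes.covariates)
        hits = {e.node_b: e for e in res.edges}
        assert genus in hits
        assert hits[genus].sign == 1
        assert hits[genus].q < 0.05


class TestMetaboliteScreens:
    def test_association_with_either_bmi_measure_suffices(self):
        rng = np.random.default_rng(4)
        n = 300
        ids = [f"S{i:03d}" for i in range(n)]
        pct = pd.DataFrame({3.0: rng.uniform(0, 100, n)}, index=ids)
        ph = make_phenotypes(pct, rng)
        cat = ph.bmi_category[3.0].to_numpy()
        # metabolite tracks the category, with noise too weak for percentile
        ab = pd.DataFrame({"metX": np.exp(0.8 * cat + 0.3 * rng.normal(size=n)),
                           "metY": np.exp(rng.normal(size=n))}, index=ids)
        met = make_metabolome(ab, pathway="pwX")
        res = metabolite_bmi_screen(met, ph, age=3.0, alpha=0.01)
        assert "metX" in res.extra["metabolites"]
        assert "pwX" in res.extra["pathways_of_interest"]

    def test_min_omics_selection_rule(self):
        rng = np.random.default_rng(8)
        n = 400
        ids = [f"S{i:03d}" for i in range(n)]
        snp1 = rng.binomial(2, 0.4, n).astype(float)
        snp2 = rng.binomial(2, 0.4, n).astype(float)
        genus_log = rng.normal(size=n)
        # met_two_snps tracks both SNPs (one omic type); met_cross tracks
        # a SNP and a genus (two types)
        ab = pd.DataFrame(
            {
                "met_two_snps": np.exp(0.6 * snp1 + 0.6 * snp2 + 0.2 * rng.normal(size=n)),
                "met_cross": np.exp(0.6 * snp1 + 0.6 * genus_log + 0.2 * rng.normal(size=n)),
            },
            index=ids,
        )
        met = make_metabolome(ab, pathway="pw1")
        ph = make_phenotypes(pd.DataFrame({3.0: rng.uniform(0, 100, n)}, index=ids), rng)
        gt = make_genotype(np.column_stack([snp1, snp2]), sample_ids=ids,
                           snp_ids=["rs1", "rs2"])
        gv = pd.DataFrame({"gA": genus_log}, index=ids)
        res = cross_omic_metabolite_tests(
            met, ["pw1"], ph, gv, ["gA"], gt, ["rs1", "rs2"], min_omics=2,
        )
        assert res.extra["selected_metabolites"] == ["met_cross"]
        partners = {(e.node_a, e.node_b) for e in res.edges}
        assert ("met_cross", "rs1") in partners and ("met_cross", "gA") in partners
        assert all(a != "met_two_snps" for a, _ in partners)

    def test_planted_chain_recovers_signed_edges(self, loop_cohort):
        model = MultiOmicsIntegration.from_cohort(loop_cohort)
        results = model.fit(seed=0)
        met = next(e.target[1] for e in loop_cohort.truth if e.target[0] == "metabolite")
        snp = next(e.source[1] for e in loop_cohort.truth if e.source[0] == "snp")
        sel = results.cross_omic.extra["selected_metabolites"]
        assert met in sel
        edge_signs = {(e.node_a, e.node_b): e.sign for e in results.cross_omic.edges}
        assert edge_signs.get((met, snp)) == 1
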