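"""Generator contracts: determinism, null calibration, effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from omicloops import (
    CohortConfig,
    PlantedEffect,
    default_config,
    fit_lm,
    plant_coherent_loop,
    simulate_cohort,
)
from omicloops._utils import standardize
from omicloops.simulate import LdPair, SnpSpec, _toposort_effects


def tiny_config(**kw):
    defaults = dict(n_samples=80, n_snps=6, n_genera=5, n_metabolites=5,
                    sequencing_depth=300, seed=7)
    defaults.update(kw)
    return default_config(**defaults)


def test_same_config_and_seed_reproduces_cohort_exactly():
    a = simulate_cohort(tiny_config())
    b = simulate_cohort(tiny_config())
    pd.testing.assert_frame_equal(a.genotype.mac, b.genotype.mac)
    for age in a.microbiome:
        pd.testing.assert_frame_equal(a.microbiome[age].counts, b.microbiome[age].counts)
    pd.testing.assert_frame_equal(a.metabolome.abundance, b.metabolome.abundance)
    pd.testing.assert_frame_equal(a.phenotypes.bmi_percentile, b.phenotypes.bmi_percentile)
    pd.testing.assert_frame_equal(a.phenotypes.covariates, b.phenotypes.covariates)


def test_different_seed_changes_draws():
    a = simulate_cohort(tiny_config(seed=1))
    b = simulate_cohort(tiny_config(seed=2))
    assert not a.genotype.mac.equals(b.genotype.mac)


@pytest.mark.parametrize(
    "kw, match",
    [
        (dict(n_samples=0), "n_samples"),
        (dict(n_genera=0), "n_genera"),
        (dict(missingness={"bmi": 1.0}), "missingness"),
    ],
)
def test_invalid_configuration_rejected(kw, match):
    with pytest.raises(ValueError, match=match):
        tiny_config(**kw)


def test_unachievable_ld_target_names_the_pair():
    panel = [
        SnpSpec("rsA", "G1", "1", 100, 0.2),
        SnpSpec("rsB", "G1", "1", 200, 0.4),
    ]
    with pytest.raises(ValueError, match="rsA.*rsB"):
        CohortConfig(n_samples=50, snp_panel=panel,
                     ld_pairs=[LdPair("rsA", "rsB", 0.95)],
                     metabolite_panel=tiny_config().metabolite_panel)


def test_ld_pair_hits_target_correlation():
    cfg = tiny_config(n_samples=3000, missingness={"genotype": 0.0})
    cohort = simulate_cohort(cfg)
    pair = cfg.ld_pairs[0]
    r = cohort.genotype.mac[pair.snp_a].corr(cohort.genotype.mac[pair.snp_b])
    assert abs(r - pair.r) < 0.04


def test_missingness_is_flagged_not_zeroed():
    cohort = simulate_cohort(tiny_config(n_samples=300))
    assert cohort.genotype.mac.isna().to_numpy().mean() == pytest.approx(0.05, abs=0.03)
    # microbiome missingness removes whole rows at an age, never zero-fills
    for age, mb in cohort.microbiome.items():
        assert len(mb.counts) < 300
        assert (mb.counts.sum(axis=1) > 0).all()
    assert len(cohort.metabolome.sample_ids) < 300
    assert cohort.phenotypes.bmi_percentile.isna().to_numpy().mean() > 0


def test_null_cohort_snp_bmi_calibration(null_cohort):
    """Without planted effects SNP-BMI tests are null-calibrated."""
    mac = null_cohort.genotype.mac
    pct = null_cohort.phenotypes.bmi_percentile
    cov = null_cohort.phenotypes.covariates
    pvals, corrs = [], []
    for age in pct.columns:
        y = pct[age]
        for snp in mac.columns:
            fit = fit_lm(y.to_numpy(), mac[snp].to_numpy(), cov)
            pvals.append(fit.p)
            corrs.append(pd.concat([y, mac[snp]], axis=1).corr().iloc[0, 1])
    corrs = np.asarray(corrs)
    assert abs(np.nanmean(corrs)) < 0.02
    frac = np.mean(np.asarray(pvals) < 0.01)
    # binomial 99% bounds around 0.01 over len(pvals) tests
    m = len(pvals)
    bound = 0.01 + 2.58 * np.sqrt(0.01 * 0.99 / m)
    assert frac <= bound + 1e-12


def test_planted_snp_bmi_effect_recovered_within_3_se():
    cfg = tiny_config(n_samples=500, missingness={"genotype": 0, "bmi": 0,
                                                  "microbiome": 0, "metabolome": 0})
    snp = cfg.snp_panel[2].snp_id
    eff = PlantedEffect(source=("snp", snp), target=("bmi", "bmi"), effect_size=0.5)
    cfg = CohortConfig(**{**cfg.__dict__, "planted_effects": [eff]})
    cohort = simulate_cohort(cfg)
    x = standardize(cohort.genotype.mac[snp].to_numpy())
    for age in cohort.phenotypes.bmi_percentile.columns:
        z = norm.ppf(cohort.phenotypes.bmi_percentile[age].to_numpy() / 100.0)
        fit = fit_lm(z, x)
        assert abs(fit.beta - 0.5) < 3 * fit.se


def test_planted_effect_validation():
    with pytest.raises(ValueError, match="different omic kinds"):
        PlantedEffect(("genus", "g"), ("genus", "h"), 0.5)
    with pytest.raises(ValueError, match="exogenous"):
        PlantedEffect(("bmi", "bmi"), ("snp", "rs1"), 0.5)
    with pytest.raises(ValueError, match="nonzero"):
        PlantedEffect(("snp", "rs1"), ("bmi", "bmi"), 0.0)


def test_planted_effect_must_reference_panel_members():
    cfg = tiny_config()
    eff = PlantedEffect(("snp", "rs_not_there"), ("bmi", "bmi"), 0.5)
    with pytest.raises(ValueError, match="unknown SNP"):
        CohortConfig(**{**cfg.__dict__, "planted_effects": [eff]})


class TestPlantCoherentLoop:
    def test_triangle_all_positive_plants_three_edges(self):
        cfg = plant_coherent_loop(tiny_config(), ("snp", "metabolite", "bmi"), (1, 1, 1))
        assert len(cfg.planted_effects) == 3
        kinds = {(e.source[0], e.target[0]) for e in cfg.planted_effects}
        assert kinds == {("snp", "metabolite"), ("metabolite", "bmi"), ("snp", "bmi")}

    def test_two_negatives_one_positive_accepted(self):
        cfg = plant_coherent_loop(tiny_config(), ("snp", "metabolite", "genus"), (-1, 1, -1))
        assert len(cfg.planted_effects) == 3
        assert int(np.prod([np.sign(e.effect_size) for e in cfg.planted_effects])) == 1

    def test_incoherent_sign_product_rejected(self):
        with pytest.raises(ValueError, match="sign product"):
            plant_coherent_loop(tiny_config(), ("snp", "metabolite", "bmi"), (1, 1, -1))

    def test_repeated_omic_type_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            plant_coherent_loop(tiny_config(), ("snp", "metabolite", "metabolite"), (1, 1, 1))

    def test_cycle_rotated_to_snp_root(self):
        cfg = plant_coherent_loop(tiny_config(), ("metabolite", "snp", "bmi"), (1, 1, 1))
        assert all(e.source[0] != "bmi" or e.target[0] != "snp" for e in cfg.planted_effects)
        assert sum(e.source[0] == "snp" for e in cfg.planted_effects) == 2


def test_directed_cycle_of_effects_is_rejected():
    effs = [
        PlantedEffect(("genus", "a"), ("metabolite", "b"), 0.5),
        PlantedEffect(("metabolite", "b"), ("bmi", "bmi"), 0.5),
        PlantedEffect(("bmi", "bmi"), ("genus", "a"), 0.5),
    ]
    with pytest.raises(ValueError, match="directed cycle"):
        _toposort_effects(effs)
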