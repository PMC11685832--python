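import numpy as np
import pandas as pd
import pytest

from omicloops import default_config, plant_coherent_loop, simulate_cohort
from omicloops.tables import GenotypeTable, MetaboliteTable, PhenotypeSeries


@pytest.fixture(scope="session")
def loop_cohort():
    """Cohort with a planted coherent SNP-metabolite-BMI triangle (n=400)."""
    cfg = default_config(
        n_samples=400, n_snps=12, n_genera=20, n_metabolites=24,
        sequencing_depth=2000, seed=42,
    )
    cfg = plant_coherent_loop(cfg, ("snp", "metabolite", "bmi"), (1, 1, 1), effect_size=0.6)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects (n=500, lean panels)."""
    cfg = default_config(
        n_samples=500, n_snps=30, n_genera=12, n_metabolites=12,
        sequencing_depth=1000, seed=7,
    )
    return simulate_cohort(cfg)


def make_genotype(mac: np.ndarray, sample_ids=None, snp_ids=None, gene="GENE1") -> GenotypeTable:
    mac = np.asarray(mac, dtype=float)
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(mac.shape[0])]
    snp_ids = snp_ids or [f"rs{i}" for i in range(mac.shape[1])]
    ann = pd.DataFrame(
        {"chrom": "1", "position": np.arange(1, mac.shape[1] + 1) * 1000, "gene": gene},
        index=snp_ids,
    )
    return GenotypeTable(pd.DataFrame(mac, index=sample_ids, columns=snp_ids), ann)


def make_phenotypes(percentile: pd.DataFrame, rng=None) -> PhenotypeSeries:
    from omicloops.tables import bmi_category_from_percentile

    rng = rng or np.random.default_rng(0)
    n = len(percentile)
    cov = pd.DataFrame(
        {
            "race": rng.choice(["a", "b", "c"], size=n),
            "sex": rng.choice(["f", "m"], size=n),
            "site": rng.choice(["s1", "s2"], size=n),
        },
        index=percentile.index,
    )
    cat = pd.DataFrame(
        bmi_category_from_percentile(percentile.to_numpy()),
        index=percentile.index, columns=percentile.columns,
    )
    return PhenotypeSeries(percentile, cat, cov)


def make_metabolome(abundance: pd.DataFrame, pathway="pw1", super_pathway="lipid"):
    pmap = pd.DataFrame(
        {"pathway": pathway, "super_pathway": super_pathway}, index=abundance.columns
    )
    return MetaboliteTable(abundance, pmap)
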