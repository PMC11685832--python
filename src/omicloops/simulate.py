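"""Synthetic multi-omic cohort generator with plantable cross-omic effects.

The generator emulates the data structure of a longitudinal birth-cohort
integration study: ~676 children with candidate-gene SNP panels (including
LD-correlated pairs), compositional genus-level 16S counts at ages 0.5, 1, 3
and 4 years, a plasma metabolome at age 3, BMI percentiles/categories at ages
2-8, categorical covariates (race, sex, study site), and enough per-omic
missingness that only a minority of samples carry complete multi-omic data.

Ground-truth cross-omic effect chains ("planted effects") are injected as
linear shifts on the latent, pre-noise scale, so every downstream screening
stage can be validated by parameter recovery, and sign-coherent loops can be
planted with :func:`plant_coherent_loop`.

Model sketch (per sample s):

* genotype: MAC ~ Binomial(2, MAF); an LD pair copies its partner column and
  resamples a fraction of entries to hit the target correlation.
* microbiome, age a: latent genus log-baseline eta = mu_g + core_g(s) +
  sigma_age * eps; counts ~ Dirichlet-multinomial over softmax(eta).
* metabolome: log abundance = mu_m + core_m(s) + sigma_met * eps.
* BMI: latent z(s, a) = core_b(s) + tau * AR1(rho) noise, unit variance under
  the null; percentile = 100 * Phi(z), category by pediatric cutpoints.

A planted effect source->target adds ``effect_size * standardize(core_source)``
to the target's core latent, so ``effect_size`` is a standardized slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import check_unique, standardize, substream
from .tables import (
    GenotypeTable,
    MetaboliteTable,
    MicrobiomeCounts,
    PhenotypeSeries,
    SUPER_PATHWAYS,
    bmi_category_from_percentile,
)

__all__ = [
    "SnpSpec",
    "LdPair",
    "MetaboliteSpec",
    "PlantedEffect",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "simulate_cohort",
    "plant_coherent_loop",
]

PLANTABLE_SOURCES = ("snp", "genus", "metabolite", "bmi")
#: map planted-effect variable kinds to network omic types
KIND_TO_OMIC = {"snp": "genotype", "genus": "microbiome",
                "metabolite": "metabolite", "bmi": "bmi"}


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    gene: str
    chrom: str
    position: int
    maf: float


@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    r: float


@dataclass(frozen=True)
class MetaboliteSpec:
    metabolite_id: str
    pathway: str
    super_pathway: str


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth linear effect between variables of different omic kinds.

    ``source``/``target`` are ``(kind, identifier)`` pairs with kind one of
    snp | genus | metabolite | bmi. ``effect_size`` is the standardized slope
    of the target latent on the standardized source latent. ``ages`` records
    the ages at which the effect acts (None = all target ages).
    """

    source: tuple
    target: tuple
    effect_size: float
    ages: tuple | None = None

    def __post_init__(self):
        skind, _ = self.source
        tkind, _ = self.target
        if skind not in PLANTABLE_SOURCES or tkind not in PLANTABLE_SOURCES:
            raise ValueError(f"unknown variable kind in {self}")
        if skind == tkind:
            raise ValueError("source and target must be of different omic kinds")
        if tkind == "snp":
            raise ValueError("genotype is exogenous: a SNP cannot be an effect target")
        if self.effect_size == 0:
            raise ValueError("effect_size must be nonzero")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort (validated on construction)."""

    n_samples: int
    snp_panel: list
    ld_pairs: list = field(default_factory=list)
    microbiome_ages: tuple = (0.5, 1.0, 3.0, 4.0)
    n_genera: int = 100
    sequencing_depth: int = 10_000
    metabolite_panel: list = field(default_factory=list)
    metabolome_age: float = 3.0
    bmi_ages: tuple = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    covariate_levels: dict = field(
        default_factory=lambda: {
            "race": ("white", "black", "hispanic", "other"),
            "sex": ("female", "male"),
            "site": ("site1", "site2", "site3"),
        }
    )
    missingness: dict = field(
        default_factory=lambda: {
            "genotype": 0.05, "microbiome": 0.20, "metabolome": 0.25, "bmi": 0.15,
        }
    )
    planted_effects: list = field(default_factory=list)
    seed: int = 0
    # latent-scale nuisance parameters
    genus_baseline_sd: float = 1.5
    genus_age_sd: float = 0.5
    metabolite_sd: float = 0.5
    dirichlet_concentration: float = 200.0
    bmi_noise_weight: float = 0.5
    bmi_ar1_rho: float = 0.8

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not self.snp_panel:
            raise ValueError("snp_panel is empty")
        if self.n_genera <= 0:
            raise ValueError("n_genera must be positive")
        if not self.metabolite_panel:
            raise ValueError("metabolite_panel is empty")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        check_unique([s.snp_id for s in self.snp_panel], "snp ids")
        check_unique([m.metabolite_id for m in self.metabolite_panel], "metabolite ids")
        for s in self.snp_panel:
            if not (0.0 < s.maf <= 0.5):
                raise ValueError(f"MAF for {s.snp_id} must be in (0, 0.5]")
        for k, v in self.missingness.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"missingness[{k!r}] must be in [0, 1)")
        mafs = {s.snp_id: s.maf for s in self.snp_panel}
        for pair in self.ld_pairs:
            if pair.snp_a not in mafs or pair.snp_b not in mafs:
                raise ValueError(f"LD pair references unknown SNP: {pair}")
            if not (0.0 < pair.r <= 1.0):
                raise ValueError(f"LD target correlation out of (0, 1]: {pair}")
            if abs(mafs[pair.snp_a] - mafs[pair.snp_b]) > 1e-12:
                raise ValueError(
                    f"unachievable LD target for pair ({pair.snp_a}, {pair.snp_b}): "
                    f"minor-allele frequencies differ ({mafs[pair.snp_a]} vs "
                    f"{mafs[pair.snp_b]})"
                )
        genus_ids = set(self._genus_ids())
        met_ids = {m.metabolite_id for m in self.metabolite_panel}
        for eff in self.planted_effects:
            for kind, ident in (eff.source, eff.target):
                if kind == "snp" and ident not in mafs:
                    raise ValueError(f"planted effect references unknown SNP {ident}")
                if kind == "genus" and ident not in genus_ids:
                    raise ValueError(f"planted effect references unknown genus {ident}")
                if kind == "metabolite" and ident not in met_ids:
                    raise ValueError(f"planted effect references unknown metabolite {ident}")

    def _genus_ids(self) -> list[str]:
        width = max(3, len(str(self.n_genera)))
        return [f"Genus_{i + 1:0{width}d}" for i in range(self.n_genera)]


def default_config(
    n_samples: int = 676,
    n_snps: int = 96,
    n_genera: int = 100,
    n_metabolites: int = 200,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """A study-scale default cohort configuration.

    96 SNPs spread over 12 candidate genes (8 per gene) with MAFs drawn once
    from a reproducible stream, one LD pair (r = 0.95), 100 genera, 200
    metabolites across 40 pathways in the five standard super-pathways.
    """
    rng = substream(seed, "default-config")
    genes = [f"GENE{g + 1:02d}" for g in range(12)]
    snp_panel = []
    for i in range(n_snps):
        gene = genes[i % len(genes)]
        snp_panel.append(
            SnpSpec(
                snp_id=f"rs{100000 + i}",
                gene=gene,
                chrom=str(1 + (i % len(genes)) % 22),
                position=1_000_000 + 5_000 * i,
                maf=float(np.round(rng.uniform(0.05, 0.5), 3)),
            )
        )
    # one LD pair with matched MAF, mirroring a correlated-MAC SNP pair
    if n_snps >= 2:
        snp_panel[1] = replace(snp_panel[1], maf=snp_panel[0].maf,
                               gene=snp_panel[0].gene, chrom=snp_panel[0].chrom)
        ld_pairs = [LdPair(snp_panel[0].snp_id, snp_panel[1].snp_id, 0.95)]
    else:
        ld_pairs = []
    supers = [sp for sp in SUPER_PATHWAYS if sp != "other"]
    n_pathways = max(1, n_metabolites // 5)
    metabolite_panel = []
    for i in range(n_metabolites):
        pw = i % n_pathways
        metabolite_panel.append(
            MetaboliteSpec(
                metabolite_id=f"met_{i + 1:04d}",
                pathway=f"pathway_{pw + 1:03d}",
                super_pathway=supers[pw % len(supers)],
            )
        )
    cfg = dict(
        n_samples=n_samples,
        snp_panel=snp_panel,
        ld_pairs=ld_pairs,
        n_genera=n_genera,
        metabolite_panel=metabolite_panel,
        seed=seed,
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its ground-truth planted effects."""

    genotype: GenotypeTable
    microbiome: dict  # age -> MicrobiomeCounts
    metabolome: MetaboliteTable
    phenotypes: PhenotypeSeries
    truth: list
    config: CohortConfig
    latents: dict = field(default_factory=dict, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotype.mac.index)


def _toposort_effects(effects) -> list:
    """Order planted effects so each target is shifted after its sources."""
    nodes = set()
    for e in effects:
        nodes.add(e.source)
        nodes.add(e.target)
    incoming = {n: set() for n in nodes}
    for e in effects:
        incoming[e.target].add(e.source)
    order: list = []
    ready = sorted(n for n in nodes if not incoming[n])
    pending = dict(incoming)
    while ready:
        n = ready.pop(0)
        order.append(n)
        for m in sorted(pending):
            if n in pending[m]:
                pending[m] = pending[m] - {n}
                if not pending[m] and m not in order and m not in ready:
                    ready.append(m)
        ready.sort()
    if len(order) < len(nodes):
        raise ValueError(
            "planted effects form a directed cycle; plant loops through a "
            "chain rooted at an exogenous variable (see plant_coherent_loop)"
        )
    rank = {n: i for i, n in enumerate(order)}
    return sorted(effects, key=lambda e: rank[e.target])


def _simulate_genotype(config: CohortConfig, sample_ids) -> GenotypeTable:
    rng = substream(config.seed, "genotype")
    n = config.n_samples
    mac = {}
    for spec in config.snp_panel:
        mac[spec.snp_id] = rng.binomial(2, spec.maf, size=n).astype(float)
    for pair in config.ld_pairs:
        # copy the partner then resample a fraction 1-r of entries
        maf = {s.snp_id: s.maf for s in config.snp_panel}[pair.snp_b]
        copied = mac[pair.snp_a].copy()
        resample = rng.random(n) > pair.r
        copied[resample] = rng.binomial(2, maf, size=int(resample.sum()))
        mac[pair.snp_b] = copied
    df = pd.DataFrame(mac, index=sample_ids)
    ann = pd.DataFrame(
        {
            "chrom": [s.chrom for s in config.snp_panel],
            "position": [s.position for s in config.snp_panel],
            "gene": [s.gene for s in config.snp_panel],
        },
        index=[s.snp_id for s in config.snp_panel],
    )
    return GenotypeTable(df, ann)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort from a validated configuration.

    Identical config + seed reproduces the cohort bit-for-bit; every stage
    draws from its own named substream so adding a stage never perturbs
    another's draws.
    """
    config.validate()
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    genotype = _simulate_genotype(config, sample_ids)
    genus_ids = config._genus_ids()
    met_ids = [m.metabolite_id for m in config.metabolite_panel]

    # raw (pre-effect) core latents per variable
    rng_g = substream(config.seed, "genus-core")
    rng_m = substream(config.seed, "metabolite-core")
    rng_b = substream(config.seed, "bmi-core")
    cores: dict[tuple, np.ndarray] = {}
    for g in genus_ids:
        cores[("genus", g)] = rng_g.standard_normal(n)
    for m in met_ids:
        cores[("metabolite", m)] = rng_m.standard_normal(n)
    tau = config.bmi_noise_weight
    cores[("bmi", "bmi")] = np.sqrt(1.0 - tau**2) * rng_b.standard_normal(n)
    for spec in config.snp_panel:
        cores[("snp", spec.snp_id)] = genotype.mac[spec.snp_id].to_numpy(dtype=float)

    # inject planted effects in dependency order on the core latents;
    # BMI effects restricted to a strict age subset act later, at the
    # per-age latent level, not on the persistent core
    def _age_restricted(eff) -> bool:
        if eff.target[0] != "bmi" or eff.ages is None:
            return False
        return set(float(a) for a in eff.ages) != set(float(a) for a in config.bmi_ages)

    for eff in _toposort_effects(config.planted_effects):
        if _age_restricted(eff):
            continue
        tkey = ("bmi", "bmi") if eff.target[0] == "bmi" else eff.target
        skey = ("bmi", "bmi") if eff.source[0] == "bmi" else eff.source
        cores[tkey] = cores[tkey] + eff.effect_size * standardize(cores[skey])

    # microbiome counts per age: Dirichlet-multinomial over softmax latents
    rng_mb = substream(config.seed, "microbiome")
    genus_mu = substream(config.seed, "genus-baseline").normal(
        0.0, config.genus_baseline_sd, size=len(genus_ids)
    )
    microbiome = {}
    for age in config.microbiome_ages:
        eta = np.empty((n, len(genus_ids)))
        for j, g in enumerate(genus_ids):
            eta[:, j] = genus_mu[j] + cores[("genus", g)] + rng_mb.normal(
                0.0, config.genus_age_sd, size=n
            )
        w = np.exp(eta - eta.max(axis=1, keepdims=True))
        alpha = config.dirichlet_concentration * w / w.sum(axis=1, keepdims=True)
        counts = np.empty((n, len(genus_ids)), dtype=np.int64)
        depths = rng_mb.poisson(config.sequencing_depth, size=n)
        for i in range(n):
            p = rng_mb.dirichlet(np.maximum(alpha[i], 1e-8))
            counts[i] = rng_mb.multinomial(max(int(depths[i]), 1), p)
        microbiome[float(age)] = pd.DataFrame(counts, index=sample_ids, columns=genus_ids)

    # metabolome (single age): log-normal abundances
    rng_met = substream(config.seed, "metabolome")
    met_mu = substream(config.seed, "metabolite-baseline").normal(0.0, 1.0, size=len(met_ids))
    log_ab = np.empty((n, len(met_ids)))
    for j, m in enumerate(met_ids):
        log_ab[:, j] = met_mu[j] + cores[("metabolite", m)] + rng_met.normal(
            0.0, config.metabolite_sd, size=n
        )
    metabolome_values = pd.DataFrame(np.exp(log_ab), index=sample_ids, columns=met_ids)

    # BMI latent: persistent core + AR(1) age noise, unit variance under null
    rng_bmi = substream(config.seed, "bmi-trajectory")
    rho = config.bmi_ar1_rho
    ages = list(config.bmi_ages)
    ar = np.empty((n, len(ages)))
    ar[:, 0] = rng_bmi.standard_normal(n)
    for t in range(1, len(ages)):
        ar[:, t] = rho * ar[:, t - 1] + np.sqrt(1 - rho**2) * rng_bmi.standard_normal(n)
    z = cores[("bmi", "bmi")][:, None] + tau * ar
    # age-restricted BMI effects act on the listed ages only
    for eff in config.planted_effects:
        if _age_restricted(eff):
            skey = ("bmi", "bmi") if eff.source[0] == "bmi" else eff.source
            src = eff.effect_size * standardize(cores[skey])
            act = set(float(a) for a in eff.ages)
            for t, a in enumerate(ages):
                if float(a) in act:
                    z[:, t] += src
    percentile = 100.0 * norm.cdf(z)

    # covariates
    rng_cov = substream(config.seed, "covariates")
    cov = pd.DataFrame(
        {
            name: rng_cov.choice(list(levels), size=n)
            for name, levels in config.covariate_levels.items()
        },
        index=sample_ids,
    )

    # missingness, applied independently per omic (per age where relevant)
    rng_miss = substream(config.seed, "missingness")
    gmiss = config.missingness.get("genotype", 0.0)
    mac = genotype.mac.copy()
    if gmiss > 0:
        mask = rng_miss.random(mac.shape) < gmiss
        vals = mac.to_numpy(dtype=float)
        vals[mask] = np.nan
        mac = pd.DataFrame(vals, index=mac.index, columns=mac.columns)
        genotype = GenotypeTable(mac, genotype.annotations)

    mb_tables = {}
    mb_miss = config.missingness.get("microbiome", 0.0)
    for age, counts in microbiome.items():
        observed = rng_miss.random(n) >= mb_miss
        kept = counts.loc[observed]
        kept = kept.loc[kept.sum(axis=1) > 0]
        mb_tables[age] = MicrobiomeCounts(kept, age_years=age)

    met_miss = config.missingness.get("metabolome", 0.0)
    observed = rng_miss.random(n) >= met_miss
    pathway_map = pd.DataFrame(
        {
            "pathway": [m.pathway for m in config.metabolite_panel],
            "super_pathway": [m.super_pathway for m in config.metabolite_panel],
        },
        index=met_ids,
    )
    metabolome = MetaboliteTable(metabolome_values.loc[observed], pathway_map)

    bmi_miss = config.missingness.get("bmi", 0.0)
    pct = percentile.copy()
    if bmi_miss > 0:
        pct[rng_miss.random(pct.shape) < bmi_miss] = np.nan
    pct_df = pd.DataFrame(pct, index=sample_ids, columns=[float(a) for a in ages])
    cat_df = pd.DataFrame(
        bmi_category_from_percentile(pct), index=sample_ids, columns=[float(a) for a in ages]
    )
    phenotypes = PhenotypeSeries(
        bmi_percentile=pct_df,
        bmi_category=cat_df,
        covariates=cov,
        allowed_levels={k: tuple(v) for k, v in config.covariate_levels.items()},
    )

    latents = {"bmi_z": pd.DataFrame(z, index=sample_ids, columns=[float(a) for a in ages]),
               "cores": cores}
    return SyntheticCohort(
        genotype=genotype,
        microbiome=mb_tables,
        metabolome=metabolome,
        phenotypes=phenotypes,
        truth=list(config.planted_effects),
        config=config,
        latents=latents,
    )


def plant_coherent_loop(
    config: CohortConfig,
    node_types,
    signs,
    effect_size: float = 0.6,
    node_ids: dict | None = None,
) -> CohortConfig:
    """Return a config whose planted effects realise a sign-coherent loop.

    ``node_types`` is an ordered list of 3 or 4 distinct omic kinds
    (snp | genus | metabolite | bmi); ``signs[i]`` is the sign of the cycle
    edge between node i and node (i+1) mod k. The product of the signs must
    be +1 — an incoherent cycle is not realizable by a consistent latent
    chain. If a SNP is among the types, the cycle is rotated so it is the
    (exogenous) root.

    ``node_ids`` optionally maps a kind to a concrete panel identifier;
    defaults pick the first panel member of each kind (for SNPs, the first
    SNP not in any LD pair).
    """
    node_types = [str(t) for t in node_types]
    signs = [int(s) for s in signs]
    k = len(node_types)
    if k not in (3, 4):
        raise ValueError("a loop has 3 or 4 nodes")
    if len(signs) != k:
        raise ValueError("need one sign per cycle edge")
    if any(s not in (-1, 1) for s in signs):
        raise ValueError("signs must be +1 or -1")
    if len(set(node_types)) != k:
        raise ValueError("loop node types must be distinct")
    if int(np.prod(signs)) != 1:
        raise ValueError(
            "sign product is -1: an incoherent loop cannot be realised by a "
            "consistent chain of latent effects"
        )
    if "snp" in node_types and node_types[0] != "snp":
        r = node_types.index("snp")
        node_types = node_types[r:] + node_types[:r]
        signs = signs[r:] + signs[:r]

    node_ids = dict(node_ids or {})
    in_ld = {p.snp_a for p in config.ld_pairs} | {p.snp_b for p in config.ld_pairs}
    defaults = {
        "snp": next(
            (s.snp_id for s in config.snp_panel if s.snp_id not in in_ld),
            config.snp_panel[0].snp_id,
        ),
        "genus": config._genus_ids()[0],
        "metabolite": config.metabolite_panel[0].metabolite_id,
        "bmi": "bmi",
    }
    ids = {t: node_ids.get(t, defaults[t]) for t in node_types}

    root = (node_types[0], ids[node_types[0]])
    effects = []
    # chain root -> n1 -> ... -> n_{k-1}
    for i in range(k - 1):
        src = (node_types[i], ids[node_types[i]]) if i else root
        tgt = (node_types[i + 1], ids[node_types[i + 1]])
        effects.append(PlantedEffect(source=src, target=tgt,
                                     effect_size=signs[i] * abs(effect_size)))
    # closing edge root -> n_{k-1}; its sign is consistent because the
    # product of all k signs is +1
    effects.append(
        PlantedEffect(
            source=root,
            target=(node_types[-1], ids[node_types[-1]]),
            effect_size=signs[-1] * abs(effect_size),
        )
    )
    return replace(config, planted_effects=list(config.planted_effects) + effects)


def write_truth(cohort: SyntheticCohort, path) -> None:
    """Dump the planted ground truth as JSON."""
    records = [
        {
            "source_kind": e.source[0],
            "source_id": e.source[1],
            "target_kind": e.target[0],
            "target_id": e.target[1],
            "effect_size": e.effect_size,
            "ages": list(e.ages) if e.ages is not None else None,
        }
        for e in cohort.truth
    ]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))
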