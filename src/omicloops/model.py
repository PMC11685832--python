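"""Model/Results interface to the three-phase integration pipeline.

:class:`MultiOmicsIntegration` is built from the four sample-aligned tables
(or directly from a simulated cohort); :meth:`~MultiOmicsIntegration.fit`
runs the three phases — (1) targeted mGWAS, the persistent SNP-BMI scan and
genus differential abundance; (2) the two-step metabolite screen; (3) signed
network assembly and sign-coherent loop detection — followed by the 70/30
predictive cross-validation of the loop variables, and returns an
:class:`IntegrationResults` carrying every stage table, the network, the
loops and the CV report, with a ``summary()`` overview.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import io as oio
from .associations import (
    collapse_correlated_snps,
    cross_omic_metabolite_tests,
    differential_abundance,
    metabolite_bmi_screen,
    persistent_bmi_scan,
    targeted_mgwas,
    tss_log,
)
from .crossval import evaluate_mse, fit_loop_models, split_samples
from .features import compute_features
from .network import build_network, find_loops, loop_null_count, loops_to_json
from .simulate import SyntheticCohort

logger = logging.getLogger("omicloops")

__all__ = ["PipelineSettings", "MultiOmicsIntegration", "IntegrationResults"]


@dataclass
class PipelineSettings:
    """All tunable thresholds of the pipeline, with the study defaults."""

    candidate_genes: tuple | None = None  # None = every gene in the panel
    n_components: int = 2
    feature_names: tuple = ("richness", "shannon", "mcpc1", "mcpc2")
    bonferroni_alpha: float = 0.05
    suggestive_p: float = 1e-5
    persistence_alpha: float = 0.01
    k_consecutive: int = 5
    require_consistent_sign: bool = True
    q_threshold: float = 0.05
    prevalence_min: float = 0.1
    metabolite_alpha: float = 0.01
    min_omics: int = 2
    r_threshold: float = 0.9
    metabolome_age: float = 3.0
    loop_sizes: tuple = (3, 4)
    distinct_types_required: bool = True
    cv_fraction: float = 0.7
    cv_min_samples: int = 20
    null_permutations: int = 0  # >0 adds a loop-count sign permutation null

    def validate(self) -> None:
        for name in ("bonferroni_alpha", "persistence_alpha", "q_threshold",
                     "metabolite_alpha", "suggestive_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0 < self.cv_fraction < 1):
            raise ValueError("cv_fraction must be in (0, 1)")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must be in (0, 1]")
        if self.k_consecutive < 1 or self.min_omics < 1:
            raise ValueError("k_consecutive and min_omics must be >= 1")
        if not (0 <= self.prevalence_min < 1):
            raise ValueError("prevalence_min must be in [0, 1)")


class MultiOmicsIntegration:
    """Three-phase genotype-microbiome-metabolome-BMI integration model."""

    def __init__(self, genotype, microbiome, metabolome, phenotypes,
                 settings: PipelineSettings | None = None):
        self.genotype = genotype
        self.microbiome = dict(microbiome)
        self.metabolome = metabolome
        self.phenotypes = phenotypes
        self.settings = settings or PipelineSettings()
        self.settings.validate()

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, settings=None) -> "MultiOmicsIntegration":
        return cls(cohort.genotype, cohort.microbiome, cohort.metabolome,
                   cohort.phenotypes, settings)

    @classmethod
    def from_directory(cls, indir, settings=None) -> "MultiOmicsIntegration":
        genotype, microbiome, metabolome, phenotypes, report = oio.read_tables(indir)
        logger.info("loaded cohort:\n%s", report)
        return cls(genotype, microbiome, metabolome, phenotypes, settings)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0) -> "IntegrationResults":
        s = self.settings
        cov = self.phenotypes.covariates

        candidate = (
            self.genotype.restrict_genes(s.candidate_genes)
            if s.candidate_genes is not None
            else self.genotype
        )
        features = {
            age: compute_features(mb, k=s.n_components)
            for age, mb in sorted(self.microbiome.items())
        }
        snp_groups = collapse_correlated_snps(self.genotype, s.r_threshold)

        mgwas = targeted_mgwas(
            candidate, features, cov.loc[cov.index.intersection(self.genotype.mac.index)],
            alpha=s.bonferroni_alpha, suggestive=s.suggestive_p,
            feature_names=s.feature_names,
        )
        persistence = persistent_bmi_scan(
            candidate, self.phenotypes, alpha=s.persistence_alpha,
            k_consecutive=s.k_consecutive,
            require_consistent_sign=s.require_consistent_sign,
        )
        snps_of_interest = sorted(
            {e.node_a for e in mgwas.edges} | {e.node_a for e in persistence.edges}
        )

        diff_edges, diff_tables = [], []
        for age in sorted(self.microbiome):
            res = differential_abundance(
                self.microbiome[age], self.genotype, snps_of_interest, cov,
                q_threshold=s.q_threshold, prevalence_min=s.prevalence_min,
            )
            diff_edges.extend(res.edges)
            if len(res.table):
                diff_tables.append(res.table)
        diff_table = pd.concat(diff_tables, ignore_index=True) if diff_tables else pd.DataFrame()
        genera_of_interest = sorted({e.node_b for e in diff_edges})

        screen = metabolite_bmi_screen(
            self.metabolome, self.phenotypes, age=s.metabolome_age,
            alpha=s.metabolite_alpha,
        )
        age_key = self._nearest_microbiome_age(s.metabolome_age)
        genus_values = (
            tss_log(self.microbiome[age_key].counts, prevalence_min=0.0)
            if age_key is not None
            else pd.DataFrame(index=self.genotype.mac.index)
        )
        cross = cross_omic_metabolite_tests(
            self.metabolome, screen.extra["pathways_of_interest"], self.phenotypes,
            genus_values, genera_of_interest, self.genotype, snps_of_interest,
            age=s.metabolome_age, alpha=s.metabolite_alpha, min_omics=s.min_omics,
        )

        selected = set(cross.extra["selected_metabolites"])
        edges = (
            list(mgwas.edges)
            + list(persistence.edges)
            + list(diff_edges)
            + [e for e in screen.edges if e.node_a in selected]
            + list(cross.edges)
        )
        network = build_network(edges)
        loops = find_loops(network, sizes=s.loop_sizes,
                           distinct_types_required=s.distinct_types_required)
        meaningful = [lp for lp in loops if lp.meaningful]
        null = (
            loop_null_count(network, n_permutations=s.null_permutations, seed=seed,
                            sizes=s.loop_sizes,
                            distinct_types_required=s.distinct_types_required)
            if s.null_permutations
            else None
        )

        cv = self._cross_validate(meaningful, features, snp_groups, genus_values, seed)

        return IntegrationResults(
            model=self,
            settings=s,
            seed=seed,
            features=features,
            snp_groups=snp_groups,
            mgwas=mgwas,
            persistence=persistence,
            diffabund_edges=diff_edges,
            diffabund_table=diff_table,
            metabolite_screen=screen,
            cross_omic=cross,
            snps_of_interest=snps_of_interest,
            genera_of_interest=genera_of_interest,
            edges=network.edges,
            network=network,
            loops=loops,
            loop_null=null,
            cv=cv,
        )

    def _nearest_microbiome_age(self, age):
        if not self.microbiome:
            return None
        return min(self.microbiome, key=lambda a: abs(a - age))

    def loop_variable_values(self, loops, features=None, genus_values=None) -> pd.DataFrame:
        """Materialise the loop-member variables per sample at the CV age.

        SNP nodes -> MAC; genus nodes -> log TSS abundance at the microbiome
        age nearest the metabolome age; metabolite nodes -> log abundance;
        BMI nodes -> the node's own measure at the metabolome age; mGWAS
        feature nodes -> the feature at its encoded age.
        """
        s = self.settings
        if genus_values is None:
            age_key = self._nearest_microbiome_age(s.metabolome_age)
            genus_values = (
                tss_log(self.microbiome[age_key].counts, prevalence_min=0.0)
                if age_key is not None else pd.DataFrame()
            )
        index = self.phenotypes.bmi_percentile.index
        cols = {}
        nodes = sorted({(n, t) for lp in loops for n, t in zip(lp.nodes, lp.omic_types)})
        for node, typ in nodes:
            if typ == "genotype":
                cols[node] = self.genotype.mac[node].reindex(index)
            elif typ == "metabolite":
                ab = self.metabolome.abundance[node].reindex(index).to_numpy(dtype=float)
                logs = np.full(ab.shape, np.nan)
                np.log(ab, out=logs, where=np.isfinite(ab) & (ab > 0))
                cols[node] = pd.Series(logs, index=index)
            elif typ == "bmi":
                measure = node.replace("BMI_", "")
                wide = self.phenotypes.measure(measure)
                col = [c for c in wide.columns if float(c) == float(s.metabolome_age)]
                cols[node] = wide[col[0]].reindex(index) if col else pd.Series(np.nan, index=index)
            elif typ == "microbiome":
                if node in genus_values.columns:
                    cols[node] = genus_values[node].reindex(index)
                elif features is not None and "_age" in node:
                    feat, _, agestr = node.rpartition("_age")
                    age = float(agestr)
                    frame = features[age].frame() if age in features else None
                    cols[node] = (
                        frame[feat].reindex(index) if frame is not None and feat in frame
                        else pd.Series(np.nan, index=index)
                    )
                else:
                    cols[node] = pd.Series(np.nan, index=index)
        return pd.DataFrame(cols, index=index)

    def _cross_validate(self, meaningful, features, snp_groups, genus_values, seed):
        if not meaningful:
            logger.info("no meaningful loops: cross-validation skipped")
            return None
        values = self.loop_variable_values(meaningful, features, genus_values)
        values = values.dropna(axis=1, how="all")
        usable = values.index[values.notna().any(axis=1)]
        if len(usable) < self.settings.cv_min_samples:
            logger.warning("too few samples for cross-validation")
            return None
        train, test = split_samples(list(values.index), self.settings.cv_fraction, seed)
        models = fit_loop_models(values, self.phenotypes.covariates, train,
                                 snp_groups=snp_groups)
        if not models:
            return None
        return evaluate_mse(models, values, self.phenotypes.covariates, test,
                            train_ids=train, seed=seed)


@dataclass
class IntegrationResults:
    """Everything the fitted pipeline produced."""

    model: MultiOmicsIntegration
    settings: PipelineSettings
    seed: int
    features: dict
    snp_groups: object
    mgwas: object
    persistence: object
    diffabund_edges: list
    diffabund_table: pd.DataFrame
    metabolite_screen: object
    cross_omic: object
    snps_of_interest: list
    genera_of_interest: list
    edges: list
    network: object
    loops: list
    loop_null: object
    cv: object

    @property
    def meaningful_loops(self) -> list:
        return [lp for lp in self.loops if lp.meaningful]

    def summary(self) -> str:
        s = self.settings
        m = self.mgwas.extra.get("m", 0)
        thr = self.mgwas.extra.get("bonferroni_threshold", float("nan"))
        lines = [
            "Multi-omic co-association network integration",
            "=" * 46,
            f"samples: {len(self.model.genotype.mac)}  SNPs: {len(self.model.genotype.snp_ids)}"
            f"  genera: {len(next(iter(self.model.microbiome.values())).genus_ids) if self.model.microbiome else 0}"
            f"  metabolites: {len(self.model.metabolome.metabolite_ids) if self.model.metabolome else 0}",
            "",
            f"Phase 1 - targeted mGWAS: {m} tests, Bonferroni p < {thr:.3g}",
            f"  significant edges: {sum(1 for e in self.mgwas.edges if e.tier == 'significant')}"
            f"  suggestive (p < {s.suggestive_p:g}): "
            f"{sum(1 for e in self.mgwas.edges if e.tier == 'suggestive')}",
            f"Phase 1 - persistent SNP-BMI scan (p < {s.persistence_alpha:g}, "
            f">= {s.k_consecutive} consecutive ages): {len(self.persistence.edges)} edges",
            f"Phase 1 - differential abundance (q < {s.q_threshold:g}): "
            f"{len(self.diffabund_edges)} edges; genera of interest: "
            f"{len(self.genera_of_interest)}",
            f"Phase 2 - metabolite-BMI screen (p < {s.metabolite_alpha:g}): "
            f"{len(self.metabolite_screen.extra.get('metabolites', []))} metabolites in "
            f"{len(self.metabolite_screen.extra.get('pathways_of_interest', []))} pathways of interest",
            f"Phase 2 - cross-omic selection (>= {s.min_omics} omics): "
            f"{len(self.cross_omic.extra.get('selected_metabolites', []))} metabolites",
            "",
            f"Phase 3 - network: {len(self.network.nodes)} nodes, "
            f"{len(self.edges)} edges",
            f"  loops found: {len(self.loops)}; meaningful (sign product +1): "
            f"{len(self.meaningful_loops)}",
        ]
        for lp in self.meaningful_loops:
            signs = "".join("+" if sgn > 0 else "-" for sgn in lp.signs)
            lines.append(f"    {' - '.join(lp.nodes)}  signs ({signs})")
        if self.loop_null is not None:
            lines.append(
                f"  sign-permutation null: observed {self.loop_null.observed}, "
                f"exceedance p = {self.loop_null.exceedance_p:.3g}"
            )
        if self.cv is not None:
            lines.append("")
            lines.append(
                f"Cross-validation ({s.cv_fraction:.0%} train, seed {self.seed}): "
                f"{len(self.cv.mse_percent)} leave-one-variable-out models, "
                f"{self.cv.n_test_complete} complete-case test samples "
                f"({self.cv.test_complete_fraction:.0%} of test set)"
            )
            for v in sorted(self.cv.mse_percent):
                mse = self.cv.mse_percent[v]
                base = self.cv.baseline_mse_percent.get(v)
                if mse is not None:
                    lines.append(f"    {v}: MSE {mse:.2f}%  (mean-predictor {base:.2f}%)")
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write every stage table, the network, loops and CV report."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}

        for age, feats in sorted(self.features.items()):
            p = outdir / f"features_age{age:g}.tsv"
            feats.frame().to_csv(p, sep="\t", index_label="sample_id")
            files[f"features_age{age:g}"] = p
            p2 = outdir / f"loadings_age{age:g}.tsv"
            feats.mcpc_loadings.to_csv(p2, sep="\t", index_label="genus")
            files[f"loadings_age{age:g}"] = p2
        for name, table in (
            ("mgwas_tests", self.mgwas.table),
            ("persistence_tests", self.persistence.table),
            ("diffabund_tests", self.diffabund_table),
            ("metabolite_screen_tests", self.metabolite_screen.table),
            ("cross_omic_tests", self.cross_omic.table),
        ):
            p = outdir / f"{name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            files[name] = p
        oio.write_edges(self.edges, outdir / "edges.tsv")
        files["edges"] = outdir / "edges.tsv"
        self.network.to_graphml(outdir / "network.graphml")
        files["network"] = outdir / "network.graphml"
        loops_to_json(self.loops, outdir / "loops.json")
        files["loops"] = outdir / "loops.json"
        if self.cv is not None:
            self.cv.to_json(outdir / "cv_report.json")
            files["cv_report"] = outdir / "cv_report.json"
            self.cv.summary_frame().to_csv(outdir / "cv_summary.tsv", sep="\t", index=False)
            files["cv_summary"] = outdir / "cv_summary.tsv"
        counts = {
            "mgwas_edges": len(self.mgwas.edges),
            "persistence_edges": len(self.persistence.edges),
            "diffabund_edges": len(self.diffabund_edges),
            "metabolite_edges": len(self.cross_omic.edges),
            "network_edges": len(self.edges),
            "loops": len(self.loops),
            "meaningful_loops": len(self.meaningful_loops),
        }
        oio.write_manifest(outdir / "manifest.json", asdict(self.settings), self.seed,
                           files, counts)
        files["manifest"] = outdir / "manifest.json"
        return files

    def plot_network(self, ax=None, layout_seed: int = 0):
        """Draw the co-association network coloured by omic type."""
        import matplotlib.pyplot as plt
        import networkx as nx

        g = self.network.graph
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        palette = {"genotype": "#1f77b4", "microbiome": "#2ca02c",
                   "metabolite": "#d62728", "bmi": "#9467bd"}
        pos = nx.spring_layout(g, seed=layout_seed)
        colors = [palette[g.nodes[n]["omic_type"]] for n in g.nodes]
        styles = ["solid" if g.edges[e]["sign"] > 0 else "dashed" for e in g.edges]
        nx.draw_networkx_nodes(g, pos, node_color=colors, ax=ax, node_size=250)
        for (u, v), style in zip(g.edges, styles):
            nx.draw_networkx_edges(g, pos, edgelist=[(u, v)], style=style, ax=ax)
        nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
        ax.set_axis_off()
        return ax
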