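"""Sample-aligned omic data containers.

Four tables cover the cohort: SNP minor-allele counts with gene annotations,
per-age genus-level 16S count tables, a metabolite relative-abundance table
with a pathway / super-pathway map, and a longitudinal BMI phenotype table
carrying the adjustment covariates (race, sex, study site).

All containers wrap pandas DataFrames indexed by sample identifier and
validate their domain invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_unique

SUPER_PATHWAYS = ("amino acid", "carbohydrate", "lipid", "nucleotide", "xenobiotic", "other")

#: CDC-style pediatric BMI percentile cutpoints -> ordinal category 0..3
#: (<5 underweight, 5-<85 healthy, 85-<95 overweight, >=95 obese).
BMI_CATEGORY_CUTPOINTS = (5.0, 85.0, 95.0)


def bmi_category_from_percentile(percentile):
    """Map BMI percentile(s) in [0, 100] to the ordinal category 0-3.

    Missing percentiles map to missing categories.
    """
    p = np.asarray(percentile, dtype=float)
    cat = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    cat[ok] = np.digitize(p[ok], BMI_CATEGORY_CUTPOINTS)
    return cat


@dataclass
class GenotypeTable:
    """Samples x SNPs minor-allele counts (MAC) with per-SNP annotations.

    mac : DataFrame of values in {0, 1, 2} or NaN (missing), indexed by
        sample id, columns are SNP ids.
    annotations : DataFrame indexed by SNP id with columns
        ``chrom``, ``position`` (1-based), ``gene``.
    """

    mac: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        check_unique(self.mac.index, "sample ids")
        check_unique(self.mac.columns, "snp ids")
        vals = self.mac.to_numpy(dtype=float)
        bad = np.argwhere(~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"genotype values must be 0/1/2 or missing; offending cell "
                f"(sample={self.mac.index[r]!r}, snp={self.mac.columns[c]!r}, "
                f"value={vals[r, c]!r})"
            )
        missing_ann = set(self.mac.columns) - set(self.annotations.index)
        if missing_ann:
            raise ValueError(f"SNPs without annotation: {sorted(missing_ann)}")
        for col in ("chrom", "position", "gene"):
            if col not in self.annotations.columns:
                raise ValueError(f"annotation table lacks column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mac.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.mac.columns)

    def restrict_genes(self, genes) -> "GenotypeTable":
        """Subset to the SNPs annotated to any of the given gene symbols."""
        keep = self.annotations.index[self.annotations["gene"].isin(set(genes))]
        keep = [s for s in self.mac.columns if s in set(keep)]
        return GenotypeTable(self.mac[keep], self.annotations.loc[keep])


@dataclass
class MicrobiomeCounts:
    """Genus-level 16S count table for one sampling age.

    counts : DataFrame of non-negative integers, samples x genera.
    age_years : the sampling age of this table.

    Samples absent at this age are simply not rows here; a retained row must
    have positive total reads.
    """

    counts: pd.DataFrame
    age_years: float

    def __post_init__(self) -> None:
        check_unique(self.counts.index, "sample ids")
        check_unique(self.counts.columns, "genus ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = vals.astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                bad = np.argwhere(as_float != np.round(as_float))[0]
                raise ValueError(
                    f"non-integer microbiome count at "
                    f"(sample={self.counts.index[bad[0]]!r}, "
                    f"genus={self.counts.columns[bad[1]]!r})"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative microbiome counts")
        totals = vals.sum(axis=1)
        if (totals == 0).any():
            empty = list(self.counts.index[totals == 0])
            raise ValueError(f"samples with zero total reads: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class MetaboliteTable:
    """Plasma metabolite relative abundances with the pathway hierarchy.

    abundance : DataFrame of non-negative reals, samples x metabolites.
    pathway_map : DataFrame indexed by metabolite id with columns
        ``pathway`` and ``super_pathway`` (one of SUPER_PATHWAYS).
    """

    abundance: pd.DataFrame
    pathway_map: pd.DataFrame

    def __post_init__(self) -> None:
        check_unique(self.abundance.index, "sample ids")
        check_unique(self.abundance.columns, "metabolite ids")
        vals = self.abundance.to_numpy(dtype=float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValueError("negative metabolite abundances")
        unmapped = set(self.abundance.columns) - set(self.pathway_map.index)
        if unmapped:
            raise ValueError(f"metabolites without pathway mapping: {sorted(unmapped)}")
        bad_sp = set(self.pathway_map["super_pathway"]) - set(SUPER_PATHWAYS)
        if bad_sp:
            raise ValueError(f"unknown super-pathways: {sorted(bad_sp)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def pathway_of(self, metabolite_id: str) -> str:
        return str(self.pathway_map.loc[metabolite_id, "pathway"])

    def metabolites_in_pathways(self, pathways) -> list[str]:
        keep = self.pathway_map.index[self.pathway_map["pathway"].isin(set(pathways))]
        return [m for m in self.abundance.columns if m in set(keep)]


COVARIATE_NAMES = ("race", "sex", "site")


@dataclass
class PhenotypeSeries:
    """Longitudinal BMI phenotypes plus the model covariates.

    bmi_percentile : DataFrame samples x ages, values in [0, 100] or NaN.
    bmi_category : DataFrame samples x ages, ordinal 0-3 or NaN.
    covariates : DataFrame with categorical columns race, sex, site,
        complete for every sample (every model adjusts for them).
    """

    bmi_percentile: pd.DataFrame
    bmi_category: pd.DataFrame
    covariates: pd.DataFrame
    allowed_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_unique(self.bmi_percentile.index, "sample ids")
        if list(self.bmi_percentile.index) != list(self.bmi_category.index) or list(
            self.bmi_percentile.index
        ) != list(self.covariates.index):
            raise ValueError("phenotype tables must share one sample index")
        p = self.bmi_percentile.to_numpy(dtype=float)
        finite = p[np.isfinite(p)]
        if ((finite < 0) | (finite > 100)).any():
            raise ValueError("BMI percentile outside [0, 100]")
        c = self.bmi_category.to_numpy(dtype=float)
        finite = c[np.isfinite(c)]
        if not np.isin(finite, (0.0, 1.0, 2.0, 3.0)).all():
            raise ValueError("BMI category must be ordinal 0-3")
        for col in COVARIATE_NAMES:
            if col not in self.covariates.columns:
                raise ValueError(f"missing covariate column {col!r}")
            if self.covariates[col].isna().any():
                raise ValueError(f"covariate {col!r} has missing values")
            if self.allowed_levels.get(col):
                unknown = set(self.covariates[col]) - set(self.allowed_levels[col])
                if unknown:
                    raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bmi_percentile.index)

    @property
    def ages(self) -> list[float]:
        return [float(a) for a in self.bmi_percentile.columns]

    def measure(self, name: str) -> pd.DataFrame:
        """Return the samples x ages table for 'percentile' or 'category'."""
        if name == "percentile":
            return self.bmi_percentile
        if name == "category":
            return self.bmi_category
        raise KeyError(f"unknown BMI measure {name!r}")
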