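"""Covariate-adjusted pairwise association stages.

Everything downstream of the raw tables runs through one ordinary
least-squares engine (:func:`fit_lm`): the targeted microbiome GWAS, the
persistent SNP-BMI scan across ages, genus differential abundance
(a MaAsLin-style TSS + log + linear model + BH recipe, reimplemented), and
the two-step metabolite screen. Every emitted edge carries the fitted slope,
its two-sided p-value, the sign of the slope, the number of samples used and
a stage provenance tag.

All models adjust for the cohort covariates (race, sex, study site),
dummy-encoded with the first level as reference, and use listwise deletion
only — no imputation anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import OMIC_TYPES
from .tables import GenotypeTable, MetaboliteTable, MicrobiomeCounts, PhenotypeSeries

logger = logging.getLogger("omicloops")

__all__ = [
    "AssociationEdge",
    "LinearFit",
    "DegenerateFitError",
    "fit_lm",
    "bh_adjust",
    "collapse_correlated_snps",
    "SnpGroups",
    "targeted_mgwas",
    "persistent_bmi_scan",
    "find_persistent_run",
    "differential_abundance",
    "metabolite_bmi_screen",
    "cross_omic_metabolite_tests",
    "encode_covariates",
    "tss_log",
]


class DegenerateFitError(ValueError):
    """Raised when a model cannot be fitted (constant exposure, too few rows)."""


@dataclass(frozen=True)
class AssociationEdge:
    """A signed association between two variables of different omic types."""

    node_a: str
    type_a: str
    node_b: str
    type_b: str
    age: object  # float, (lo, hi) tuple for a persistence run, or None
    beta: float
    se: float
    p: float
    sign: int
    stage: str
    q: float | None = None
    tier: str | None = None
    n_used: int | None = None

    def __post_init__(self):
        if self.type_a not in OMIC_TYPES or self.type_b not in OMIC_TYPES:
            raise ValueError(f"unknown omic type on edge {self.node_a}-{self.node_b}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")
        if self.sign not in (-1, 1):
            raise ValueError("edge sign must be +1 or -1")

    @property
    def key(self) -> tuple:
        """Unordered node-pair key used for merging parallel edges."""
        a = (self.node_a, self.type_a)
        b = (self.node_b, self.type_b)
        return tuple(sorted((a, b)))


@dataclass
class LinearFit:
    """OLS fit summary; ``beta``/``se``/``p`` refer to the exposure term."""

    beta: float
    se: float
    p: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    df_resid: int
    n_used: int
    dropped: list = field(default_factory=list)


def encode_covariates(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Dummy-encode categorical covariates (first level = reference)."""
    if covariates is None or covariates.shape[1] == 0:
        return covariates
    if all(np.issubdtype(dt, np.number) for dt in covariates.dtypes):
        return covariates  # already encoded
    num = covariates.select_dtypes(include=[np.number])
    cat = covariates.drop(columns=num.columns)
    parts = [num.astype(float)] if num.shape[1] else []
    if cat.shape[1]:
        parts.append(pd.get_dummies(cat.astype(str), drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # a numerically-zero p is clamped so downstream log/validation never sees 0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def fit_lm(
    response,
    exposure,
    covariates: pd.DataFrame | None = None,
    min_n: int = 10,
) -> LinearFit:
    """OLS of ``response ~ exposure + covariates`` with listwise deletion.

    Parameters
    ----------
    response, exposure
        Numeric vectors, positionally aligned (align on sample id before
        calling). Missing values in either trigger listwise deletion.
    covariates
        Optional table aligned with the vectors. Categorical columns are
        dummy-encoded with the first level as reference; numeric columns
        (e.g. pre-encoded dummies) pass through. Collinear covariate columns
        are dropped with a warning.
    min_n
        Minimum number of complete rows; fewer raises DegenerateFitError.

    Returns
    -------
    LinearFit with the exposure coefficient's slope, standard error and
    two-sided t-test p-value.
    """
    y = np.asarray(response, dtype=float).ravel()
    x = np.asarray(exposure, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("response and exposure lengths differ")

    cov = encode_covariates(covariates)
    if cov is not None and len(cov) != len(y):
        raise ValueError("covariate table length differs from vectors")
    C = cov.to_numpy(dtype=float) if cov is not None else np.empty((len(y), 0))
    cov_names = list(cov.columns) if cov is not None else []

    mask = np.isfinite(y) & np.isfinite(x)
    if C.shape[1]:
        mask &= np.isfinite(C).all(axis=1)
    n = int(mask.sum())
    if n < min_n:
        raise DegenerateFitError(f"only {n} complete rows (< {min_n})")
    y, x, C = y[mask], x[mask], C[mask]

    if np.ptp(x) == 0:
        raise DegenerateFitError("exposure is constant after listwise deletion")

    X = np.column_stack([np.ones(n), C, x])
    names = ["const"] + cov_names + ["exposure"]
    dropped: list[str] = []
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # rank-deficient: drop collinear covariate columns (constant columns,
        # duplicated levels, ...) and refit
        keep = []
        base = np.ones((n, 1))
        for j in range(C.shape[1]):
            cand = np.column_stack([base] + [C[:, k: k + 1] for k in keep]
                                   + [C[:, j: j + 1]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                keep.append(j)
            else:
                dropped.append(cov_names[j])
        if dropped:
            logger.warning("dropping collinear covariate column(s): %s", dropped)
        C = C[:, keep]
        cov_names = [cov_names[j] for j in keep]
        X = np.column_stack([np.ones(n), C, x])
        names = ["const"] + cov_names + ["exposure"]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateFitError("exposure collinear with covariates")
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise DegenerateFitError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = _p_from_t(tvals, df_resid)

    params = pd.Series(coef, index=names)
    return LinearFit(
        beta=float(coef[-1]),
        se=float(se[-1]),
        p=float(pvals[-1]),
        params=params,
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        df_resid=df_resid,
        n_used=n,
        dropped=dropped,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SnpGroups:
    """Single-linkage groups of SNPs with highly correlated MAC columns."""

    groups: list[list[str]]
    r_threshold: float

    def group_of(self, snp_id: str) -> list[str]:
        for g in self.groups:
            if snp_id in g:
                return g
        return [snp_id]

    def partners(self, snp_id: str) -> set[str]:
        """Other members of the SNP's group (excluded as its predictors)."""
        return set(self.group_of(snp_id)) - {snp_id}


def collapse_correlated_snps(genotype: GenotypeTable, r_threshold: float = 0.9) -> SnpGroups:
    """Group SNPs whose pairwise |Pearson r| of MAC >= threshold (single linkage).

    Groups are the linkage-disequilibrium proxies used downstream: members of
    one group never serve as each other's predictors in cross-validation.
    """
    if not (0.0 < r_threshold <= 1.0):
        raise ValueError("r_threshold must be in (0, 1]")
    snps = genotype.snp_ids
    corr = genotype.mac.corr().abs().to_numpy()
    # union-find over |r| >= threshold
    parent = list(range(len(snps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if np.isfinite(corr[i, j]) and corr[i, j] >= r_threshold:
                parent[find(i)] = find(j)
    buckets: dict[int, list[str]] = {}
    for i, s in enumerate(snps):
        buckets.setdefault(find(i), []).append(s)
    groups = sorted([sorted(g) for g in buckets.values()])
    return SnpGroups(groups=groups, r_threshold=r_threshold)


def _sign(beta: float) -> int:
    return 1 if beta >= 0 else -1


@dataclass
class StageResult:
    """Edges passing a stage's threshold plus the full audit table."""

    edges: list[AssociationEdge]
    table: pd.DataFrame
    extra: dict = field(default_factory=dict)


def _align(frames_and_series):
    """Intersection-align a list of pandas objects on their index."""
    idx = None
    for obj in frames_and_series:
        idx = obj.index if idx is None else idx.intersection(obj.index)
    return [obj.loc[idx] for obj in frames_and_series], idx


def targeted_mgwas(
    genotype: GenotypeTable,
    features_by_age: dict,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    suggestive: float = 1e-5,
    feature_names: tuple = ("richness", "shannon", "mcpc1", "mcpc2"),
) -> StageResult:
    """Targeted mGWAS: every candidate SNP vs every microbiome feature per age.

    The microbiome feature is the response and the SNP minor-allele count the
    exposure. The Bonferroni threshold is ``alpha / m`` with m the number of
    tests actually performed; edges below it are tier "significant", edges
    below ``suggestive`` (but not Bonferroni-significant) are tier
    "suggestive". Both tiers are emitted.
    """
    if not genotype.snp_ids:
        raise ValueError("candidate SNP panel is empty")
    cov_enc = encode_covariates(covariates)
    rows = []
    for age in sorted(features_by_age):
        feats = features_by_age[age]
        frame = feats.frame()
        use_feats = [f for f in feature_names if f in frame.columns]
        (fr, mac, cv), idx = _align([frame[use_feats], genotype.mac, cov_enc])
        for feat in use_feats:
            y = fr[feat].to_numpy(dtype=float)
            for snp in genotype.snp_ids:
                try:
                    fit = fit_lm(y, mac[snp].to_numpy(dtype=float), cv)
                except DegenerateFitError as exc:
                    logger.warning("mgwas skip %s~%s@%g: %s", feat, snp, age, exc)
                    continue
                rows.append(
                    dict(snp=snp, feature=feat, age=age, beta=fit.beta, se=fit.se,
                         p=fit.p, n_used=fit.n_used)
                )
    table = pd.DataFrame(rows)
    m = len(table)
    threshold = alpha / m if m else np.nan
    edges = []
    for _, r in table.iterrows():
        tier = None
        if r["p"] < threshold:
            tier = "significant"
        elif r["p"] < suggestive:
            tier = "suggestive"
        if tier is None:
            continue
        edges.append(
            AssociationEdge(
                node_a=r["snp"], type_a="genotype",
                node_b=f"{r['feature']}_age{r['age']:g}", type_b="microbiome",
                age=float(r["age"]), beta=float(r["beta"]), se=float(r["se"]),
                p=float(r["p"]), sign=_sign(r["beta"]), stage="mgwas",
                tier=tier, n_used=int(r["n_used"]),
            )
        )
    edges.sort(key=lambda e: (e.p, e.node_a, e.node_b))
    return StageResult(edges=edges, table=table,
                       extra={"m": m, "bonferroni_threshold": threshold})


def find_persistent_run(
    pvals, betas, alpha: float, k_consecutive: int, require_consistent_sign: bool = True
):
    """Locate the best run of >= k consecutive tests with p < alpha.

    A run additionally requires a constant slope sign when
    ``require_consistent_sign``. Returns ``(start, end)`` inclusive indices of
    the best qualifying run (longest, ties broken by smallest p inside), or
    None.
    """
    p = np.asarray(pvals, dtype=float)
    b = np.asarray(betas, dtype=float)
    runs = []
    i = 0
    while i < len(p):
        if not (np.isfinite(p[i]) and p[i] < alpha):
            i += 1
            continue
        j = i
        while (
            j + 1 < len(p)
            and np.isfinite(p[j + 1])
            and p[j + 1] < alpha
            and (not require_consistent_sign or _sign(b[j + 1]) == _sign(b[i]))
        ):
            j += 1
        if j - i + 1 >= k_consecutive:
            runs.append((i, j))
        i = j + 1
    if not runs:
        return None
    return min(runs, key=lambda r: (-(r[1] - r[0]), np.nanmin(p[r[0] : r[1] + 1])))


def persistent_bmi_scan(
    genotype: GenotypeTable,
    phenotypes: PhenotypeSeries,
    alpha: float = 0.01,
    k_consecutive: int = 5,
    require_consistent_sign: bool = True,
) -> StageResult:
    """Scan for SNP-BMI associations persisting over consecutive ages.

    BMI percentile and BMI category are scanned separately. An edge is
    emitted for a SNP iff some run of >= ``k_consecutive`` consecutive ages
    has p < ``alpha`` (with a constant slope sign when required); the edge
    carries the slope and p of the run's best age and records the run's age
    range.
    """
    ages = sorted(phenotypes.ages)
    if len(ages) < k_consecutive:
        logger.warning("only %d BMI ages available (< %d): empty persistence scan",
                       len(ages), k_consecutive)
        return StageResult(edges=[], table=pd.DataFrame())
    cov_enc = encode_covariates(phenotypes.covariates)
    rows = []
    edges = []
    for measure in ("percentile", "category"):
        wide = phenotypes.measure(measure)
        (wide_a, mac, cv), idx = _align([wide, genotype.mac, cov_enc])
        for snp in genotype.snp_ids:
            x = mac[snp].to_numpy(dtype=float)
            per_age = []
            for age in ages:
                y = wide_a[age].to_numpy(dtype=float) if age in wide_a.columns else (
                    wide_a[[c for c in wide_a.columns if float(c) == age][0]].to_numpy(dtype=float)
                )
                try:
                    fit = fit_lm(y, x, cv)
                    per_age.append((age, fit.beta, fit.se, fit.p, fit.n_used))
                except DegenerateFitError as exc:
                    logger.warning("persistence skip %s %s@%g: %s", snp, measure, age, exc)
                    per_age.append((age, np.nan, np.nan, np.nan, 0))
            for age, beta, se, p, n in per_age:
                rows.append(dict(snp=snp, measure=measure, age=age, beta=beta,
                                 se=se, p=p, n_used=n))
            run = find_persistent_run(
                [r[3] for r in per_age], [r[1] for r in per_age],
                alpha, k_consecutive, require_consistent_sign,
            )
            if run is None:
                continue
            i0, i1 = run
            best = min(per_age[i0 : i1 + 1], key=lambda r: r[3])
            edges.append(
                AssociationEdge(
                    node_a=snp, type_a="genotype",
                    node_b=f"BMI_{measure}", type_b="bmi",
                    age=(float(per_age[i0][0]), float(per_age[i1][0])),
                    beta=float(best[1]), se=float(best[2]), p=float(best[3]),
                    sign=_sign(best[1]), stage="persistence", n_used=int(best[4]),
                )
            )
    edges.sort(key=lambda e: (e.p, e.node_a, e.node_b))
    return StageResult(edges=edges, table=pd.DataFrame(rows))


def tss_log(counts: pd.DataFrame, prevalence_min: float = 0.0) -> pd.DataFrame:
    """Total-sum scaling to proportions, half-minimum pseudocount, natural log.

    Genera below the prevalence floor (fraction of samples with a nonzero
    count) are dropped. Zero proportions are replaced per genus by half its
    minimum nonzero proportion before the log, mirroring the standard
    multivariable microbiome association recipe.
    """
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    props = counts.to_numpy(dtype=float) / totals[:, None]
    prevalence = (props > 0).mean(axis=0)
    keep = prevalence >= prevalence_min
    props = props[:, keep]
    cols = list(np.asarray(counts.columns)[keep])
    out = np.empty_like(props)
    for j in range(props.shape[1]):
        col = props[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            out[:, j] = np.nan
            continue
        fill = nz.min() / 2.0
        out[:, j] = np.log(np.where(col > 0, col, fill))
    return pd.DataFrame(out, index=counts.index, columns=cols)


def differential_abundance(
    counts: MicrobiomeCounts,
    genotype: GenotypeTable,
    snp_ids,
    covariates: pd.DataFrame,
    q_threshold: float = 0.05,
    prevalence_min: float = 0.1,
) -> StageResult:
    """Genus differential abundance vs MAC of the SNPs of interest, one age.

    Per genus: TSS proportions, half-minimum pseudocount, log, covariate-
    adjusted OLS on MAC; BH correction across genera within each SNP at this
    age; edges reported at q < ``q_threshold``.
    """
    log_ab = tss_log(counts.counts, prevalence_min=prevalence_min)
    if log_ab.shape[1] == 0:
        logger.warning("no genus passes prevalence >= %g at age %g",
                       prevalence_min, counts.age_years)
        return StageResult(edges=[], table=pd.DataFrame())
    cov_enc = encode_covariates(covariates)
    rows = []
    edges = []
    (ab, mac, cv), idx = _align([log_ab, genotype.mac, cov_enc])
    for snp in snp_ids:
        snp_rows = []
        x = mac[snp].to_numpy(dtype=float)
        for genus in ab.columns:
            try:
                fit = fit_lm(ab[genus].to_numpy(dtype=float), x, cv)
            except DegenerateFitError as exc:
                logger.warning("diffabund skip %s~%s: %s", genus, snp, exc)
                continue
            snp_rows.append(dict(snp=snp, genus=genus, age=counts.age_years,
                                 beta=fit.beta, se=fit.se, p=fit.p, n_used=fit.n_used))
        if not snp_rows:
            continue
        qs = bh_adjust([r["p"] for r in snp_rows])
        for r, q in zip(snp_rows, qs):
            r["q"] = float(q)
            rows.append(r)
            if q < q_threshold:
                edges.append(
                    AssociationEdge(
                        node_a=r["snp"], type_a="genotype",
                        node_b=r["genus"], type_b="microbiome",
                        age=float(counts.age_years), beta=float(r["beta"]),
                        se=float(r["se"]), p=float(r["p"]), q=float(q),
                        sign=_sign(r["beta"]), stage="diffabund",
                        n_used=int(r["n_used"]),
                    )
                )
    edges.sort(key=lambda e: (e.p, e.node_a, e.node_b))
    return StageResult(edges=edges, table=pd.DataFrame(rows))


def _log_metabolite(series: pd.Series) -> np.ndarray:
    """Natural log of abundance; zeros filled with half the min nonzero value."""
    v = series.to_numpy(dtype=float)
    nz = v[np.isfinite(v) & (v > 0)]
    if nz.size == 0:
        return np.full_like(v, np.nan)
    fill = nz.min() / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(np.where(v > 0, v, fill))


def metabolite_bmi_screen(
    metabolome: MetaboliteTable,
    phenotypes: PhenotypeSeries,
    age: float = 3.0,
    alpha: float = 0.01,
) -> StageResult:
    """Screen log metabolite abundances against BMI at one age.

    Each metabolite is regressed (as response) on BMI percentile and, in a
    separate model, on BMI category, adjusting for covariates. Metabolites
    with p < ``alpha`` against either measure are collected; the set of their
    pathways becomes the "pathways of interest" for the cross-omic step.
    """
    cov_enc = encode_covariates(phenotypes.covariates)
    rows, edges = [], []
    hits = set()
    for measure in ("percentile", "category"):
        wide = phenotypes.measure(measure)
        col = [c for c in wide.columns if float(c) == float(age)]
        if not col:
            raise ValueError(f"BMI {measure} not available at age {age}")
        (ab, bmi, cv), idx = _align([metabolome.abundance, wide[col[0]], cov_enc])
        x = bmi.to_numpy(dtype=float)
        for met in ab.columns:
            y = _log_metabolite(ab[met])
            if np.nanstd(y) == 0:
                logger.warning("metabolite %s has zero variance; skipped", met)
                continue
            try:
                fit = fit_lm(y, x, cv)
            except DegenerateFitError as exc:
                logger.warning("metabolite screen skip %s~%s: %s", met, measure, exc)
                continue
            rows.append(dict(metabolite=met, measure=measure, age=age, beta=fit.beta,
                             se=fit.se, p=fit.p, n_used=fit.n_used,
                             pathway=metabolome.pathway_of(met)))
            if fit.p < alpha:
                hits.add(met)
                edges.append(
                    AssociationEdge(
                        node_a=met, type_a="metabolite",
                        node_b=f"BMI_{measure}", type_b="bmi",
                        age=float(age), beta=float(fit.beta), se=float(fit.se),
                        p=float(fit.p), sign=_sign(fit.beta), stage="metabolite",
                        n_used=fit.n_used,
                    )
                )
    pathways = sorted({metabolome.pathway_of(m) for m in hits})
    edges.sort(key=lambda e: (e.p, e.node_a, e.node_b))
    return StageResult(edges=edges, table=pd.DataFrame(rows),
                       extra={"pathways_of_interest": pathways, "metabolites": sorted(hits)})


def cross_omic_metabolite_tests(
    metabolome: MetaboliteTable,
    pathways_of_interest,
    phenotypes: PhenotypeSeries,
    genus_values: pd.DataFrame,
    genera_of_interest,
    genotype: GenotypeTable,
    snps_of_interest,
    age: float = 3.0,
    alpha: float = 0.01,
    min_omics: int = 2,
) -> StageResult:
    """Pairwise tests of pathway-of-interest metabolites vs all other omics.

    Every metabolite in a pathway of interest is tested (always as response,
    log scale) against each BMI measure at ``age``, each genus of interest
    (log TSS abundance at ``age``) and each SNP of interest (MAC). A
    metabolite is selected iff it is significant (p < ``alpha``) against
    variables of at least ``min_omics`` distinct other omic types; all its
    significant edges are then emitted.
    """
    if not pathways_of_interest:
        logger.warning("empty pathways_of_interest: no cross-omic metabolite tests")
        return StageResult(edges=[], table=pd.DataFrame(),
                           extra={"selected_metabolites": []})
    candidates = metabolome.metabolites_in_pathways(pathways_of_interest)
    cov_enc = encode_covariates(phenotypes.covariates)

    partners = []
    for measure in ("percentile", "category"):
        wide = phenotypes.measure(measure)
        col = [c for c in wide.columns if float(c) == float(age)]
        if col:
            partners.append((f"BMI_{measure}", "bmi", wide[col[0]]))
    for genus in sorted(genera_of_interest):
        if genus in genus_values.columns:
            partners.append((genus, "microbiome", genus_values[genus]))
    for snp in sorted(snps_of_interest):
        if snp in genotype.mac.columns:
            partners.append((snp, "genotype", genotype.mac[snp]))

    rows = []
    per_met: dict[str, list[AssociationEdge]] = {}
    for met in candidates:
        for pname, ptype, pseries in partners:
            (ab, xs, cv), idx = _align([metabolome.abundance[[met]], pseries, cov_enc])
            y = _log_metabolite(ab[met])
            try:
                fit = fit_lm(y, xs.to_numpy(dtype=float), cv)
            except DegenerateFitError as exc:
                logger.warning("cross-omic skip %s~%s: %s", met, pname, exc)
                continue
            rows.append(dict(metabolite=met, partner=pname, partner_type=ptype,
                             age=age, beta=fit.beta, se=fit.se, p=fit.p,
                             n_used=fit.n_used))
            if fit.p < alpha:
                per_met.setdefault(met, []).append(
                    AssociationEdge(
                        node_a=met, type_a="metabolite", node_b=pname, type_b=ptype,
                        age=float(age), beta=float(fit.beta), se=float(fit.se),
                        p=float(fit.p), sign=_sign(fit.beta), stage="metabolite",
                        n_used=fit.n_used,
                    )
                )
    edges, selected = [], []
    for met, met_edges in per_met.items():
        omics = {e.type_b for e in met_edges}
        if len(omics) >= min_omics:
            selected.append(met)
            edges.extend(met_edges)
    edges.sort(key=lambda e: (e.p, e.node_a, e.node_b))
    return StageResult(edges=edges, table=pd.DataFrame(rows),
                       extra={"selected_metabolites": sorted(selected)})
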