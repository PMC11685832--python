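# Methods

This note records the statistical model behind each stage, the synthetic
cohort generator's assumptions, the numerical choices, and the known
limitations. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## Association engine

Every stage fits ordinary least squares of a numeric response on one numeric
exposure plus the cohort covariates (race, sex, study site), dummy-encoded
with the first level as reference. Rows with any missing value among
response, exposure or covariates are dropped (listwise deletion; the number
of rows used is recorded on every result). The reported slope, standard
error and two-sided t-test p-value are the exposure coefficient's. A
constant exposure after deletion is a degenerate fit: the test is skipped
and logged, never silently zeroed. Collinear covariate columns are dropped
with a warning (detected lazily — a full-rank design takes a single
least-squares pass). p-values are clamped to the smallest positive float so
that downstream validity checks (p ∈ (0, 1]) and logs never see an exact
zero.

Benjamini–Hochberg q-values use the standard step-up with monotonicity
enforcement (via statsmodels). The hand-computed step-up on a worked example
is the test oracle, and the OLS engine is verified against both an explicit
(XᵀX)⁻¹Xᵀy computation and statsmodels OLS to 1e-10.

## Microbiome phenotypes

Per age we compute genus richness (number of nonzero genera), Shannon
diversity in nats over nonzero proportions, and k = 2 composition PCs.
The PCs come from a robust Aitchison PCA: the robust centered log-ratio
transform maps each nonzero count to ln(count) minus the mean ln(count)
over that sample's nonzero entries, leaving zeros as *missing* (no
pseudocounts, no rarefaction — zeros are structural missingness under this
transform, and the transform is invariant to per-sample rescaling). The
rclr matrix is column-centered on observed cells and completed by iterative
rank-k SVD imputation: missing cells start at 0 and are refilled from the
rank-k reconstruction until the reconstruction change on observed cells
falls below a relative Frobenius tolerance.

Numerical choices: tol = 1e-6, max_iter = 5000. On study-scale tables
(≈ 500–700 samples × 100 genera, ~30% zeros) convergence takes roughly
350–2000 iterations; scores computed at tolerances 1e-5 and 1e-7 correlate
beyond 0.999999, so the default is not a sensitive dial. Non-convergence
returns the current solution with a `converged=False` flag and a warning.
On a dense matrix the procedure is exactly classical PCA (verified against
scikit-learn to 1e-8); on masked rank-1 matrices it recovers the generating
factor (|r| > 0.99). Each component is sign-fixed so its largest-magnitude
loading is positive; scores are `U·s` sample coordinates, and the explained
fraction is the squared singular value over the total.

The tested mGWAS phenotype set (richness, Shannon, MCPC1, MCPC2) is
configurable; both common alpha-diversity metrics are computed because no
single one is canonical for this design.

## Screening thresholds

* mGWAS Bonferroni threshold: 0.05 / m with m the number of (SNP, feature,
  age) tests actually performed after skips — m is counted, not assumed.
  A second, *suggestive* tier at p < 10⁻⁵ is labelled separately.
* Persistence: p < 0.01 at ≥ 5 consecutive ages, additionally requiring a
  constant slope sign across the run (toggleable); the emitted edge carries
  the best age's slope/p and the run's age range.
* Differential abundance: prevalence filter at 10%, total-sum scaling,
  half-minimum pseudocount per genus (half the smallest nonzero proportion
  of that genus), natural log, OLS on MAC, BH across genera within each
  (age, SNP) family, q < 0.05. This pins one concrete multivariable
  microbiome-association recipe; tool-specific variants differ mainly in
  the pseudocount convention.
* Metabolite screens: metabolite abundances are log-transformed (zeros
  filled with half the minimum nonzero value; the generator produces
  strictly positive abundances, so this is a guard, not a modeling step).
  The metabolite is always the response and MAC / BMI / genus log-abundance
  the exposure — one orientation is fixed for reproducibility and recorded
  on each edge. "A BMI measurement" means percentile *or* category; an edge
  records which. Selection requires p < 0.01 partners in ≥ 2 distinct other
  omic types.

## Network and loops

Edges are undirected and signed by the fitted slope; the regression
orientation is provenance metadata. Only cross-omic edges are admissible.
Parallel edges for one node pair (different stages or ages) merge to the
smallest-p edge, keeping all provenance. Loops are simple cycles of 3 or 4
nodes; coherence is formalised as edge-sign product = +1, the unique rule
under which "two negative links and one positive link" is coherent and any
single discordant link is not. Type policy: 3-node loops require three
distinct omic types; 4-node loops allow at most one repeated type (this
admits cycles through two metabolites of one pathway, which occur in real
integrations); a flag relaxes the policy entirely. Enumeration canonicalises
each cycle to its lexicographically smallest rotation/reflection and is
tested against a brute-force scan of all node triples/quadruples on random
graphs. The optional null for the meaningful-loop count redraws every edge
sign uniformly from {+1, −1} with topology fixed — resampling rather than
shuffling, since shuffling preserves the sign product on a single cycle.

## Cross-validation

70/30 uniform split, deterministic under the seed. One OLS model per loop
variable, predictors = all other loop variables except members of the
response's correlated-SNP group (single-linkage groups of |Pearson r| ≥ 0.9
MAC columns), covariates always included. Training uses per-model complete
cases; the test set is restricted to samples complete across *all* loop
variables and covariates. Each variable and its predictions are min–max
normalised with training-set bounds before squaring, and MSE is reported
×100 — the only convention making percent MSE dimensionless across omics.
Genotype responses are modelled as numeric MAC and predictions are not
rounded. BMI nodes enter the CV as their own measure (percentile nodes as
percentile, category nodes as category) at the metabolome age.

## Synthetic cohort generator

The generator emulates the structure of a longitudinal pediatric multi-omic
cohort. Defaults: 676 samples; 96 SNPs over 12 candidate genes with MAFs
drawn once in (0.05, 0.5] and one LD pair at r = 0.95; 100 genera at ages
0.5/1/3/4 with mean sequencing depth 10,000; 200 metabolites in 40 pathways
across the five standard super-pathways at age 3; BMI at ages 2–8;
covariates race (4 levels), sex (2), site (3) sampled uniformly.

Per sample: MAC ~ Binomial(2, MAF); an LD partner copies its pair and
resamples a fraction 1−r of entries (requires matched MAFs — mismatches are
a configuration error naming the pair). Genus latents are log-normal
baselines (SD 1.5 across genera) plus a persistent subject component and
per-age noise (SD 0.5); counts are Dirichlet-multinomial over the softmax
of the latents with concentration 200 and Poisson depths. Metabolite log
abundances are subject latents plus noise (SD 0.5). The BMI latent is
z = subject core + 0.5·AR(1) (ρ = 0.8) with unit variance under the null;
percentile = 100·Φ(z) and category follows the standard pediatric
percentile cutpoints (<5, 5–<85, 85–<95, ≥95 → 0–3), which we adopt as the
convention since no single alternative is canonical.

Planted effects add `effect_size × standardised(source latent)` to the
target's latent with coefficient 1, so `effect_size` is a standardised
slope; effects are injected in dependency order (a directed cycle of
planted effects is rejected — loops are realised as chains rooted at an
exogenous variable, and genotype can never be a target).
`plant_coherent_loop` realises a 3–4-node cycle with requested edge signs;
it requires sign product +1, because the closing edge of a consistent
latent chain necessarily carries the product of the chain signs.

Missingness is applied independently per omic (and per age where relevant),
completely at random: genotype 5% entrywise; microbiome 20% of samples per
age (rows absent, never zero-filled); metabolome 25% of samples; BMI 15%
per (sample, age). Under these defaults the complete-case fraction of a
held-out test set at age 3 lands around 0.38–0.50 — a minority of samples
with complete multi-omic data, as in realistic cohorts.

All randomness flows through named substreams keyed by a stable hash of
(seed, stage name), so identical config + seed reproduces a cohort
bit-for-bit and adding a stage never perturbs another's draws.

What the generator does **not** emulate: population structure or kinship,
real taxon inventories or allele frequencies, phylogenetic correlation
among genera, batch effects, non-random missingness, and nonlinear
genotype–phenotype relations. Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration under its own assumptions, not
robustness to these real-data complications.

## Null calibration and the persistence run statistic

With no planted effects, each screening stage's raw p-values are
Kolmogorov–Smirnov-uniform at study scale (verified per stage in the
acceptance suite). One subtlety: the ≥5-consecutive-ages run statistic has
a per-SNP null rate of ~3×10⁻¹⁰ only when the per-age tests are
independent. The generator's default BMI trajectories are strongly
autocorrelated (a persistent subject core plus AR(1) memory — realistic for
BMI percentiles), which makes per-age tests nearly perfectly dependent and
gives the run statistic an appreciable null rate. The null-calibration
suite therefore switches the BMI model to independent ages
(`bmi_noise_weight=1, bmi_ar1_rho=0`) to realise the statistic's nominal
null; the default remains autocorrelated. The practical reading: persistence
across ages guards against one-off fluctuations, but with strongly tracking
phenotypes it is closer to a single test than to five independent ones.

## Problem sizes used in validation

The acceptance suite uses the cohort sizes the analysis is designed around:
null calibration at n = 500 with 100 SNPs, 100 genera and 200 metabolites;
200 replicates for the persistence-scan null; 100 replicates at n = 600
(15 SNPs, 25 genera, 30 metabolites) for planted-loop recovery, which
succeeds in well over 80% of replicates with 0.6-SD edges and never with a
wrong sign. `scripts/acceptance.py` runs the full pipeline once at the
default 676-sample scale with three planted loops.

## Known limitations

* No mixed models or longitudinal random effects; each age is analysed
  marginally, and the persistence criterion is the only longitudinal
  element.
* No causal orientation: edges are undirected, and a coherent loop is a
  consistency statement about signs, not evidence of mechanism.
* OLS on ordinal (BMI category) and discrete (MAC) responses is a
  pragmatic convention inherited from the design; the CV treats both as
  numeric.
* The Bonferroni denominator counts performed tests only; skipped
  degenerate fits shrink m slightly, so the threshold adapts to the data
  actually analysable.
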