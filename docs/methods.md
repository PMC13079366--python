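# Methods

This note documents the data-generating model, the estimators, the numerical
conventions, and the design choices that were genuinely open — in the spirit
of a statistical package's model documentation. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## The data-generating model

**Genetics.** A panel of `n_snps = 335` independent biallelic SNPs is drawn
with effect-allele frequencies uniform on (0.10, 0.90). Raw per-allele
schooling effects are Gaussian and rescaled so that, under Hardy–Weinberg
proportions, one SD of the true allele score shifts schooling by
`pi_first_stage = 0.26` years — the first-stage strength a polygenic
education index of this size achieves in registry-scale data. Parent pairs
are drawn per family; offspring genotypes arise by literal Mendelian
transmission (each allele a fair draw from the parent's two), with MZ twins
one meiosis duplicated and DZ twins independent meioses. There is no LD,
genotyping error, or missingness by design.

**Published score weights.** The score weights used to build the polygenic
instrument are the *discovery GWAS* per-allele estimates: truth plus
sampling noise with SE `discovery_gwas_se = 0.0022` years/allele, the
precision a multi-million-sample discovery study delivers. The weights can
additionally absorb a stratification contamination term proportional to the
between-subpopulation allele-frequency contrast — emulating a discovery
GWAS run on a structured population without adequate control. These same
published betas serve as the exposure side of the summary-level MR suite
(the two-sample layout); a same-sample exposure mode exists
(`per_snp_associations(..., exposure="sample")`) but is far noisier: with
0.26 years spread over 335 SNPs and schooling SD ≈ 2.5, a 50,000-person
sample yields per-SNP F ≈ 1.6, and harmonizing on such noisy signs distorts
MR-Egger (a sign winner's curse). This is the main respect in which passing
tests speak to the two-sample practice and not to a fully within-sample
summary MR.

**Assortative mating** is induced by Gaussian-copula rank matching within
subpopulation: father score ranks are matched to a latent variable
correlated `rho_assortative` with the mother's standardized score, giving
direct control of the spousal score correlation (hit within ±0.03 at 10,000
pairs).

**Phenotypes.** Latent schooling is
`S* = 13 + (1 + h·g)·T + a_S·A + d_S·M + strat + N(0, 2.5²)`,
rounded and clipped to the integer range [6, 23] (attainment-register
convention); `T` is the true genetic score, `A` latent ability, `M` the
standardized mid-parental score (the genetic-nurture channel), `g` the
latent gain modifier. Earnings are zero before labor-market entry at age
`S + 7` (school entry at 7, so 10 years of schooling puts entry at age 17,
the first panel age) and log-normal afterwards:
`log y_it = 11.5 + 0.136·x − 0.004·x² + β_i·S + a_Y·A + d_Y·M + Σ_j δ_j G_j
+ strat + u_i + e_it`, with potential experience `x = age − S − 7`,
`β_i = 0.08 + hetero_kappa·g (+ sex gap)`, person effect `u_i ~ N(0, 0.2²)`
and transitory noise `e_it ~ N(0, 0.3²)`.

**Mincer calibration.** Slope and curvature are pinned jointly by two
requirements of the study design: (i) age-specific returns must turn
positive near age 27 (`slope − β = 2·curv·(27 − 20)`), and (ii) the
prime-age outcome (top-3 mean over ages 34–40) must identify β — at fixed
age an extra year of schooling removes a year of experience, so the
experience term must be orthogonal to schooling in the prime-age window
(`slope = 2·curv·(30 − E[S])`). Solving both gives `curv = 0.004`,
`slope = 0.136`, which also puts the mean-earnings crossover between more-
and less-educated groups at ≈ 27.5. Without (ii) no estimator could recover
β from prime-age earnings, a mechanical consequence of the earnings
equation rather than a confounding story.

**Pleiotropy.** A seeded shuffle marks `round(pleio_fraction·m)` SNPs as
invalid; their direct log-earnings effects are `pleio_effect_mean·sign(e_j)
+ N(0, pleio_effect_sd²)`. The directional component is aligned with the
schooling-increasing allele: after the γ ≥ 0 harmonization every summary-MR
estimator sees it as a common positive intercept, which is what
"directional" means post-harmonization (a sign-symmetric direct effect
cancels and is undetectable by the Egger intercept). The default
directional magnitude (0.006 on 30% of SNPs) puts the planted intercept at
several SEs of the Egger intercept estimator, i.e. the scenario is powered
to demonstrate detection, not to sit at the boundary.

**Stratification.** Subpopulations shift allele frequencies (aligned with
the schooling-increasing allele by default — classic confounding — or with
random orientation), schooling, and log-earnings intercepts. A key
structural fact the bias experiments respect: a score re-weighted by a
within-sibling FGWAS still leaks stratification of order √m (weight noise ×
frequency contrasts) — reweighting fixes *weight* contamination, not
analysis-sample structure — so the stratified-weights scenario keeps the
outcome-side offset small (0.02 log points) relative to FGWAS-MR sampling
noise while the O(m) systematic contamination of published weights leaves
population MR biased by many SEs. Sibling-MR removes both, since subpop and
mid-parental score are family constants.

## Samples

Prime-age earnings are the mean of the top three earnings years in ages
34–40 (fewer than three observed years: average what exists). Samples:
full; sibling (families with ≥ 2 included offspring); complete DZ and MZ
twin pairs; genotyped (participation decided per family with probability
`genotyped_family_prob`, optionally correlated with parental earnings to
emulate self-selected cohort enrolment); genotyped siblings (the FGWAS
discovery set); genotyped unrelated (one offspring per genotyped family
outside the discovery sibships — disjointness is enforced by a family-id
intersection check that hard-errors on overlap). The polygenic score is
standardized within each analysis sample (a flag controls this).

## Estimators and inference

All fixed-effects estimators demean within family; covariates without
within-family variation are dropped (and reported), families without
schooling variation contribute nothing to identification but stay in n. IV
fits partial covariates out of outcome, exposure and instrument (FWL), so
the just-identified 2SLS coefficient is a ratio of cross-moments; the
first-stage partial F is the squared cluster-robust t of the instrument.

Sandwich variances use the correction `G/(G−1)·(n−1)/(n−k)`; with one
observation per cluster this reduces to HC1 (tested against statsmodels).
Default clustering follows the convention: birth cohort for pooled models,
family × birth cohort intersection for fixed-effects models; a tuple of
column names gives intersection clusters.

The Anderson–Rubin test regresses `y − b·S` (partialled) on the instrument
and refers the cluster-robust statistic to a t distribution with G − 1
degrees of freedom — the standard few-cluster reference; with ~24 birth-
cohort clusters a normal reference measurably under-covers. The CI inverts
the test by bisection from a bracket of ±10 Wald SEs, doubling until
rejection or declaring the side open-ended (flagged, not an exception).

**Summary-level MR.** IVW is the γ²/se(Γ)²-weighted average of per-SNP Wald
ratios (identical to weighted through-origin regression); Cochran's Q is
reported, never used to drop SNPs. MR-Egger is weighted least squares with a
free intercept and a multiplicative overdispersion factor bounded below by
one. The weighted median aggregates exact ties before interpolating the
cumulative-weight crossing at 0.5 (this makes it order-invariant); its SE is
a parametric bootstrap (default 1,000 draws, seeded). Mode estimators use a
normal-kernel weighted KDE with a modified-Silverman bandwidth computed from
*weighted* spread measures, and a search grid confined to the weighted
0.5–99.5% range at resolution finer than the bandwidth — both needed because
weak-SNP Wald ratios have heavy tails that would otherwise inflate the
bandwidth or coarsen the grid past the peak. The core-gene analysis ranks
SNPs by γ²/se(γ)² and reports IVW over cumulative strength deciles, the top
decile being primary.

**FGWAS.** Per-SNP family-fixed-effects regressions of schooling on
demeaned allele counts, family-clustered; SNPs without within-family
variation are omitted, not zero-filled. The re-weighted score uses surviving
SNPs only and is standardized within the estimation sample.

**UCI sensitivity.** δ is the hypothesized direct effect of one SD of the
instrument on the outcome; the adjusted outcome is `y − δ·Z`. For a single
instrument the adjusted estimate equals `β̂ − δ/first-stage` exactly (tested
to 1e−8). The breakdown δ solves `ci_low(δ) = 0` by bisection (the bound is
monotone when the first stage is positive; a non-monotone grid falls back to
a scan with a flag). Wald CIs are used inside the loop by default. The
breakdown share divides by the reduced-form association, making the
threshold dimensionless.

**Decomposition.** For integer schooling, `S = v_0 + Σ_k Δ_k·1{S ≥ v_k}`
exactly; OLS margin weights are `Δ·cov(S̃, D)` (Yitzhaki), IV weights
`Δ·cov(Z̃, D)`, each summing to `var(S̃)` and `cov(Z̃, S)` respectively
(checked as an identity, not a tolerance). Stratum weights are
`P(x)·var(S̃|x)` and `P(x)·cov(Z̃, S|x)` over sex × parental-earnings
quartiles (ties to the lower quartile). The sequential split assigns the
covariate-weighting component first, then margin weighting, then the
residual — which absorbs unobserved confounding together with
complier-vs-population averaging, the two being inseparable by
construction; components therefore sum to the gap exactly. Margin increments
within strata come from observed (confounded) regressions, with adjacent
margins pooled when a stratum-level increment is unidentified. An
`order="margin_first"` flag swaps the attribution order. The monotonicity
check reports the minimum IV margin and stratum weights; all non-negative
(within 1e−8) is a pass.

**Life cycle.** Age-specific returns re-run the chosen estimator with the
absolute earnings observed at each age as the outcome, zeros retained —
which is precisely what produces negative early-career returns. Lifetime
return is the undiscounted mean over ages; the IRR solves
`Σ_a β_a (1+r)^{−(a−a_min)} = 0` by bracketed root-finding on (−0.75, 1.5)
to 1e−6, handling roots that land exactly on grid points, returning the
root nearest zero with a warning when several exist.

## Problem sizes

The acceptance surface uses the sizes the study design calls for: ~50,000
individuals for null-scenario recovery; 20,000 two-offspring sibships for
the dynastic/assortative demonstration; 25,000 families (≈ 20,000 discovery
sibships + ≈ 5,000 singleton families as the unrelated estimation sample)
for the contaminated-weights demonstration; 500 replicates of ~1,200-person
cohorts for Anderson–Rubin coverage; three replicate panels of ~49,000 for
the balanced-pleiotropy median check, whose Monte-Carlo SE combines the
bootstrap with across-panel variation (which SNPs are invalid is itself a
Monte-Carlo draw). Unit tests run on much smaller populations.

## What the simulator does not emulate

No LD (the study's clumping step is out of scope, SNPs are independent by
construction); no genotype QC, missingness or genotyping error; no real
earnings-distribution shape beyond the qualitative concave profile and
crossover (no unemployment spells, no wage-inflation adjustment, no taxes or
tuition in the IRR); schooling is a single final value rather than
"attainment by age 33"; kinship comes from the pedigree rather than
genotype-based inference; twin zygosity is known. Passing tests therefore
certify the estimators' behavior under the stated structural model, not
robustness to the measurement pathologies of real registry data.

## Known limitations

Mode-based estimators remain the noisiest of the summary suite and are
sensitive to the bandwidth factor when invalid SNPs carry much of the
instrument strength. The FGWAS-reweighted instrument inherits √m
stratification leakage as discussed above, so it cannot by itself certify
independence in a structured sample — mirroring the fact that such designs
pair reweighting with family fixed effects or ancestry adjustment. DZ-twin
and sibling fixed effects share one estimand here (both remove exactly the
family-shared channels), so simulations cannot separate them the way
whole-genome background variation would in real data; only the MZ contrast
(identical genotypes) is structurally distinct.
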