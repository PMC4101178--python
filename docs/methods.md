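# Methods

## Scope and model overview

`ryegs` studies how well genomic selection (GS) and marker-assisted
selection (MAS) predict the genotypic value of hybrid-rye testcross
candidates, and how that accuracy depends on the relatedness between the
material used to calibrate the model and the material being predicted, and
on the number of field-trial environments (location × year combinations)
behind the phenotypes.  Because no real data ship with the package, a
first-class simulator generates populations and trials with the genetic and
experimental structure of an elite hybrid rye breeding experiment: two
bi-parental F3:4 populations of 220 lines sharing one parent (half-sibs),
testcrossed to an unrelated CMS tester, evaluated for four traits in up to
nine environments with two replications, and genotyped with roughly a
thousand biallelic markers on the seven rye linkage groups.

## Simulator

**Meiosis.** Haldane model: the crossover count on a chromosome of length
*L* cM is Poisson(*L*/100), crossover positions are uniform, there is no
interference.  An F1 between two fully homozygous parents is selfed twice
by single seed descent; each line is one F3 plant.  At a segregating locus
the F3 genotype distribution is 3/8 : 1/4 : 3/8, hence expected
heterozygosity 0.25 and dosage variance 3/4.

**Markers and parents.** Markers are placed uniformly at random (default
150 per chromosome, 120 cM per linkage group, in the range of published rye
DArT maps).  The non-shared parents differ from the shared parent at
configurable fractions of loci (defaults 0.376 and 0.557, reproducing the
394-vs-584-of-1048 segregating-marker asymmetry of the emulated
experiment).  Genotypes are coded as allele-1 dosage with a single
reference allele for all populations; the per-cross
"non-shared-parent-allele" coding differs only by per-marker reflection
2 − x, to which every downstream analysis is invariant.

**Traits.** A trait architecture holds the number of QTL (default 50,
polygenic), the target genotypic variance σ²_G, the interaction variance
σ²_GE, the plot error σ²_e, and environment/replication/block variances.
Default magnitudes for grain yield, plant height, starch and pentosan
content follow the published variance components of the emulated trial
network (`REFERENCE_ARCHITECTURES`).  QTL are drawn among segregating loci
and their normal effects are rescaled so that the realized
within-population variance of the genetic values equals σ²_G exactly
("empirical" calibration).  The alternative "theoretical" calibration
scales by the independent-loci expectation Σ 0.75·a²; it undershoots the
LD contribution of linked QTL by roughly 20 % at 50 QTL and is kept only
as an option.

**Genotype-by-environment interaction.** Two modes:

* `genetic` (default): each environment perturbs the QTL effects
  (independent normal deviations per QTL × environment, rescaled so the
  per-environment interaction variance equals σ²_GE).  Related lines then
  share their interaction deviations through their marker genotypes.  This
  is what makes prediction *within* a set of environments genuinely easier
  than transfer to unseen environments — the mechanism behind the
  location/year transfer penalty and behind the mild "overestimation" of
  same-environment cross-validation.  Standardized accuracies r_g can
  slightly exceed 1 in same-environment schemes for exactly this reason.
* `iid`: one independent normal draw per genotype × environment.  This
  matches the covariance structure assumed by the variance-component
  estimator and is used in the estimator-recovery simulations; under iid
  interaction the within/across-location schemes are equivalent by
  construction.

**Field design.** Plot value = mean + genetic value + environment effect +
interaction + replication effect + block effect + error.  Blocks are
random effects nested in replications with random line-to-block
assignment; the incomplete-block connectivity of a real alpha design is
not modeled, since the downstream model only requires replication and
block terms.  The tester contributes a constant absorbed in the mean;
no dominance or epistasis is simulated.

**Assayed marker panel.** The causal QTL loci are excluded from the marker
panel handed to the prediction methods (`TrialSimulation.marker_panel`), as
in a real assay where causal polymorphisms are tagged by linked markers.
With causal loci genotyped, a detected-QTL regression is nearly as accurate
as RR-BLUP, which no real comparison shows.

What the simulator does **not** emulate: genotyping error, segregation
distortion, selection during line development, population structure beyond
the two crosses, spatial field trends, heteroscedastic errors across
environments.  Passing tests therefore certify the estimators and the
orderings under the stated generative model, not the absolute accuracy
levels attainable on real rye data.

## Two-step phenotypic analysis

Step 1, within each environment: plot value = genotype (fixed) +
replication (random) + block (random) + error, fitted by REML; the
genotype solutions are the per-environment BLUEs and the residual is that
environment's effective error σ²_e.  Step 2, across environments, operates
on the BLUE table (equally weighted): genotype fixed gives the
across-environment BLUEs used as the response for prediction; genotype
random gives the variance components.  With one record per cell the step-2
residual mixes σ²_GE with the sampling error of the step-1 means, so the
interaction is separated by subtracting the carried-forward BLUE error.
The subtracted term is the average sampling variance of a genotype-centered
BLUE computed exactly from the step-1 GLS covariance (falling back to
σ̄²_e/n_rep when only residuals are available); the exact form matters
because the shrinkage of random block and replication effects leaks a
small amount of their variance into genotype contrasts, which would
otherwise bias σ²_GE upward by a few percent.  The result is clamped at
zero.

Derived quantities, with n_E environments and n_R replications:

* entry-mean heritability h² = σ²_G / (σ²_G + σ²_GE/n_E + σ²_e/(n_E·n_R));
* repeatability (single environment) r = σ²_g / (σ²_g + σ²_e/n_R);
* interaction ratio σ²_GE / (σ²_G + σ²_GE), which predicts how much
  accuracy is lost when predictions are transferred to unseen
  environments.

## REML engine

`VarianceComponentsModel` fits y = Xβ + Σ Z_i u_i + e with one iid variance
component per random term.  The restricted likelihood is evaluated on error
contrasts K′y (K an orthonormal null-space basis of X′), which also keeps
the per-iteration cost at the contrast dimension rather than n.
Optimization uses average-information (AI) updates with step halving; when
an AI proposal drives a component negative the component is pinned at zero
and the AI system re-solved for the remainder (an active-set refinement
that avoids the slow boundary crawl of plain EM); EM steps are the
fallback when no AI step improves the likelihood.  Convergence: relative
change of the restricted log-likelihood < 1e-8, at most 200 iterations;
non-convergence raises an error carrying the likelihood trace.  Negative
estimates are clamped at the zero boundary and flagged, matching
non-negative reporting conventions.  Fixed effects are GLS solutions at
the fitted variances; BLUPs come from the mixed-model equations.

On balanced complete layouts REML coincides with the closed-form ANOVA
method-of-moments estimators; `pheno` uses those closed forms on balanced
data (the equality is asserted against the iterative engine in the test
suite) so that the Monte-Carlo studies and the per-replicate heritability
re-estimation inside cross-validation are cheap.

## RR-BLUP

Marker effects solve Henderson's equations
[[1′1, 1′X], [X′1, X′X + λI]](μ, a)′ = (1′y, X′y)′ with
λ = m(1 − h²)/h², where m is the marker count and h² the heritability of
the estimation set, re-estimated inside every cross-validation replicate
from that replicate's own BLUE matrix (clamped to [0.01, 0.99] so λ stays
finite in degenerate replicates).  Columns are centered before solving,
which makes the intercept orthogonal to the markers; because only the
intercept is unpenalized the effect solutions are identical to the raw
uncentered system (asserted by test).  The solver uses the m-dimensional
normal equations when m ≤ 4N and the equivalent N-dimensional kernel
system otherwise; the GBLUP identity (kinship K = X_c X_c′ with matched
variance ratio) serves as an independent oracle in the tests.

## Composite interval mapping and MAS

Cofactors are chosen by forward stepwise marker regression (entry
threshold p < 0.01, at most n/5 cofactors).  On a 1-cM grid the phenotype
is regressed on an expected-QTL covariate linearly interpolated from the
flanking markers (first-order Haley–Knott approximation; beyond terminal
markers the nearest marker dosage is used), with cofactors within 10 cM of
the tested position dropped from both models.  The statistic is the
regression LOD (n/2)·log10(RSS_reduced/RSS_full); peaks above the
threshold (default 3.73, taken as a given constant) must be ≥ 20 cM apart
on a chromosome to count as distinct.  MAS-QTL predicts test lines by
multiple regression on the detected-QTL covariates, detection performed on
the estimation set only; its accuracy is standardized as
r_g = √(R²_CV/h²), capped at one with a warning.  MAS-NEUT replaces
detected QTL by randomly sampled markers spread over linkage groups (one
per group first, extras without replacement).

## Cross-validation

Genotypes are partitioned into five near-equal subsets; S1–S4 form the
estimation set and S5 the test set.  Schemes: Within-Within-Same (one
population), Within-Within-Different (ES = all of one population, TS = all
of the other; a deterministic evaluation), Across-Across (pooled folds,
stratified by population so each fold is about half from each),
Across-Within (ES = S1–S4 of both populations, TS = held-out fold of one);
an environment-count family (ES and TS phenotypes rebuilt from k randomly
drawn environments per replicate, k = 1…9, with both fold membership and
environment choice re-randomized per replicate); and a location/year
family (ES from two locations × two years or one year × four complete
locations; TS from the same or the complementary environments, with a
configurable exclusion list — by default the single-year HOH10 analog —
never entering a TS).  Accuracy per replicate is r_p = Pearson(observed TS
BLUEs, predictions); r_g = r_p/√h² uses the ES-re-estimated h² (the
full-data h² is reported alongside).  Replicates with degenerate
correlations (zero variance, < 3 pairs) are excluded from summaries and
counted.  ES/TS genotype disjointness is asserted in every replicate; all
randomness descends from one seed via `SeedSequence.spawn`, so a rerun is
bit-identical.

## Problem sizes and numerical choices

Default study size: 2 × 220 lines, 1050 markers, 9 environments, 2
replications — the size the simulator emulates.  The packaged analyses use
200 cross-validation resamples by default (5,000 in the emulated protocol;
the distributions of r_p are already stable at 200, and the resample count
is a config knob).  The Monte-Carlo recovery study uses 100 simulated
trials.  Numerical tie-breaks and tolerances: REML log-likelihood
tolerance 1e-8 with a residual floor of 1e-10 × the contrast variance;
h² clamp [0.01, 0.99] for λ; LD of monomorphic markers is reported as NaN
with a `defined = False` flag, never as 0; QC frequency bounds are
exclusive for exclusion (markers at exactly 0.05/0.95 are kept); rounding
for comparisons against printed 2-decimal values uses Python's round
(half-even).

## Known limitations

* Absolute accuracy levels are higher than on real data (simulated QTL are
  tagged by dense, error-free markers); only orderings and recovery of
  variance components are claimed.
* The two-step split of σ²_GE relies on balanced data and equal weighting
  of step-1 BLUEs; with strongly unbalanced data a one-stage fit would be
  preferable.
* CIM standard errors and QTL-effect bias (Beavis effect) are not
  corrected; detected-QTL counts at a fixed LOD are descriptive.
* Starch/pentosan heritabilities printed in the emulated study do not
  recompute exactly from their 2-decimal variance components (rounding in
  the source); the package therefore validates h² only for grain yield
  and plant height.
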