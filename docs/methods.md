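# Methods

This note records the statistical machinery, the synthetic-data model, the
numerical conventions, and the design decisions behind `rhizoadapt`.

## Community descriptors

**Rarefaction** is a single seeded multivariate-hypergeometric draw per
sample (subsampling without replacement to exactly the target depth); samples
below the depth are dropped and reported. We deliberately do not average over
repeated draws — one draw, made reproducible by the seed, matches how a
single rarefied table is carried through the rest of the analysis.

**Alpha diversity.** Richness is the count of taxa with positive counts;
Shannon entropy uses the natural log; Pielou's evenness is H/ln(richness)
and is *undefined* (NaN, not 0) for richness < 2, since ln(1) = 0.

**Distances.** Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on counts; a pair of
all-zero samples is defined as distance 0 with a warning. Weighted UniFrac
defaults to the raw (non-normalized) variant Σ_b ℓ_b·|A_b − B_b| over
branches b, where A_b, B_b are the fractions of each sample's reads
descending from b; a `normalized=True` flag divides by Σ_b ℓ_b·(A_b + B_b).
Taxa present in a table but absent from the tree are an error, never a
silent prune. On a star tree with unit branch lengths the raw variant equals
the L1 distance between the two samples' proportion vectors, which the test
suite checks exactly.

**β-dispersion** embeds the distance matrix by principal coordinates keeping
both real axes (positive eigenvalues) and imaginary axes (negative
eigenvalues); the squared distance of a sample to its group centroid is the
real-part contribution minus the imaginary-part contribution, floored at
zero (the standard correction for semi-metric dissimilarities). We use the
group *centroid*, not the spatial median; median-based implementations will
differ slightly on skewed groups.

## Distance-based inference

All inference runs on the Gower-centered matrix G = −½ J D² J (J the
centering projector). The total sum of squares equals trace(G) =
(1/n)·Σ_{i<j} d²ᵢⱼ, asserted in tests.

**PERMANOVA** uses sequential (Type-I) sums of squares: terms are added in
the user's order, each term's SS is the trace of G against the increment of
the cumulative hat matrix, and pseudo-F uses the residual mean square. Term
order therefore matters and is part of the model specification. P-values
come from free permutation of sample labels with the convention
p = (1 + b)/(1 + m); for n ≤ 8 an exact mode enumerates all n!
relabelings. Aliased terms (no added rank) raise an error naming the term.

**Moran's eigenvector maps (dbMEM).** Distances above a truncation
threshold — by default the longest edge of the minimum spanning tree, which
keeps the graph connected — are replaced by 4× the threshold; the truncated
matrix is Gower-centered and eigen-decomposed; eigenvectors with positive
eigenvalues are retained, orthonormal. Geographic distances are great-circle
(haversine, radius 6371 km) from panel coordinates; genetic distances are
the proportion of mismatching non-missing SSR loci.

**Conditioning uses a broad-scale MEM subset by default.** With ~40
genotypes, the positive-eigenvalue eigenvectors of the geographic matrix
(~25) plus those of the SSR matrix (~26) jointly span the entire
between-genotype space, so conditioning on all of them mathematically
annihilates *every* genotype-level predictor — the conditioned dbRDA could
never select anything. The default therefore keeps, per source, the
eigenvectors whose eigenvalue exceeds the mean of the positive eigenvalues
(~10 each, joint rank ~21 of 39): these carry the broad-scale
autocorrelation that conditioning is meant to remove, while leaving room for
environmental predictors to act. `mem_subset: all` restores the full basis
for users who want the over-conditioned variant.

**dbRDA.** The Gower matrix and the (z-scored) predictors are residualized
on the condition block plus intercept; constrained inertia is the trace of
the residualized G projected onto the residualized predictor space, and
conditioned + constrained + unconstrained = total holds to 1e-8 by
construction. Predictor columns collinear with the condition are dropped by
pivoted QR with a warning.

**Forward selection.** At each step every remaining candidate is tested for
its marginal addition to the current model (condition + already-selected
terms); the candidate with the smallest permutation P enters (ties broken by
larger pseudo-F), and selection stops when the best P exceeds α. The
permutation scheme permutes the *candidate* across exchangeable units,
re-residualizes it on the reduced model, and refits, leaving the residual
matrix fixed. When candidates are genotype-level covariates measured on
replicated samples, the exchangeable unit is the genotype (whole blocks of
replicates move together, via the `groups` argument); otherwise samples are
permuted freely. We chose this over permuting the residualized distance
matrix because permuted residuals regain components inside the conditioned
subspace, which makes the observed statistic systematically beat its
permutation distribution in replicated, conditioned designs — with the
candidate-permutation scheme a pure-noise genotype-level decoy is selected
at the nominal rate (≈5%), which the acceptance suite verifies. The selected
model is reported with an adonis2-style sequential variance partition.

## Mixed models

Trait models follow the crossed design: historic soil nitrogen (continuous,
z-scored — reaction norms are continuous regressions), microbe treatment,
glasshouse nitrogen, all interactions up to the three-way, with random
intercepts for genotype and block.

* **Gaussian** responses (height, biomass) are fit by REML through
  statsmodels MixedLM with the two crossed random intercepts as variance
  components. A fitted variance component below 1e-6× the residual variance
  flags the fit as singular; the term is *retained*, because dropping it
  would hide the design's pseudoreplication structure. With both variances
  at zero the fixed-effect estimates coincide with ordinary least squares
  (tested to 1e-6).
* **Per-term tests, gaussian.** `marginal` (default): Wald F on the term's
  coefficient block using the REML covariance. `sequential`: Type-I F from
  sequential projections of the GLS-whitened design (whitening by the
  estimated marginal covariance), which reduces exactly to classical
  sequential ANOVA when the random variances vanish. Denominator df follow a
  containment rule: a term constant within a random grouping is tested at
  that grouping's level (levels − rank of the grouping-level fixed design);
  all other terms use n − rank(X) − Σ(levels−1). Under the null generator
  every term's type-I error is within [0.03, 0.08] at nominal 0.05
  (acceptance suite, 500 replicates).
* **Binomial** responses (tillering) use an in-package Laplace-approximate
  maximum-likelihood logistic mixed model: joint penalized Newton for
  (β, u), Nelder–Mead over the log random-effect SDs, marginal likelihood
  ℓ − ½u'D⁻¹u − ½log det(I + Z'WZD). With no random terms it reproduces
  plain logistic regression to 1e-6. Term tests are likelihood-ratio χ²
  respecting marginality (Type II: each term against the model of all terms
  not containing it; `sequential` adds terms in order).

Diversity/abundance–environment models (`fit_env_diversity_model`) regress a
per-sample metric on the standardized genotype-level covariate with the same
random intercepts and report the slope per SD.

## Microbial effect and slope comparison

ME = (live − sterile)/sterile from genotype × glasshouse-nitrogen cell
means (raw means, no block adjustment — a block-adjusted variant is not
provided because the design is randomized across blocks and the estimand is
the plain cell contrast). Cells with fewer than 2 plants per microbe level
are dropped with a warning; a non-positive sterile mean marks the estimate
unusable.

**Uncertainty propagation.** Delta method:
Var(ME) ≈ Var(L̄)/S̄² + L̄²·Var(S̄)/S̄⁴, assuming independent cell means.
Monte Carlo (default for inference): normal draws of both cell means,
redrawing sterile draws below 5% of the observed sterile mean to keep the
simulated ratio away from the pole; a sterile-mean CV above 0.33 triggers a
heavy-tail warning. The two agree within 5% when both CVs are ≤ 10%
(verified over 100 random cases).

**Reaction norms** are unweighted OLS lines of ME on the standardized
predictor (plain fitted lines; inverse-variance weighting is an option, not
the default).

**Slope-difference test.** A parametric bootstrap: in each of n_sim
replicates, every genotype's ME in *both* environments is independently
perturbed by its propagated SE, both norms are refit, and the slope
difference recorded; the two-sided P is 2·min(Pr(Δ* ≤ 0), Pr(Δ* ≥ 0)) with
the (1+b)/(1+n_sim) convention, capped at 1. Perturbations are independent
between environments — the cells are disjoint plants, so no correlation
structure is assumed. With all SEs zero and unequal slopes the P attains its
floor 2/(1+n_sim). Under the null generator the P distribution is uniform
and the rejection rate nominal; power for the default planted
opposite-signed slopes at 10 genotypes × 10 sown replicates (~7.3 surviving)
exceeds 0.8 (both verified in the acceptance suite). The same machinery
accepts a genotype-level microbiome trait (diazotroph richness,
ammonia-oxidizer share) as the predictor.

## The synthetic generator

The generator is the package's study stand-in; its defaults *are* the study
conditions.

**Genotype panel.** Coordinates uniform over lon 26–45°, lat 36–42°; nine
environment covariates are an exponential-kernel Gaussian process over
geographic distance (default range 300 km, 30% independent nugget),
cross-correlated by a two-factor structure (soil fertility; climate), then
scaled to plausible units (e.g. soil N ≈ 1.5 ± 0.6 g/kg). SSR markers mix a
spatial process with noise (`ibd_strength` controls isolation-by-distance)
and discretize into 4 allele classes with 2% missing. Phylogenies are random
Kingman coalescents with the root-branch-length-0 convention.

**Count tables** are Dirichlet-multinomial: per-sample composition logits =
taxon baseline (SD 1.2 across taxa) + per-genotype loading + environmental
response + block shift; concentration = dispersion × composition
(dispersion 200 for 16S, 300 for nifH); read depth Poisson around the mean
(10 000 / 4 000). Replicate r of every genotype sits in block r (racks as
blocks). Calibrated effect sizes, fixed once:

| parameter | default | calibration anchor |
|---|---|---|
| `genotype_sd` | 0.236 | bisection so PERMANOVA genotype R² (Bray–Curtis, 40×5) sits mid-band 21–31% |
| `env_beta` (10% responders) | 0.5 | selected-environment dbRDA share ~1–3%, soil-N term ~1.5% |
| `block_sd` | 0.12 | small but nonzero block R² (~1–3%) |
| richness gradient | (25, 12) | expected detected nifH taxa at the soil-N extremes |
| ammonia-oxidizer share | (0.85%, 1.12%) | expected community share at the extremes |

The richness gradient is *occupancy thinning*: Bernoulli presence per taxon
per genotype with probability chosen so the expected number of occupied,
detected taxa interpolates linearly along standardized soil N; a
beta-binomial detection correction accounts for taxa present but unseen at
the sequencing depth. The ammonia-oxidizer gradient instead pins the flagged
group's expected *share*: flagged and unflagged taxa are separately
softmax-normalized and mixed at the target share, so the expectation is
exact under the count noise.

**Trait experiment.** trait = baseline·(1 + nitrogen_effect·1[high N])·
(1 + ME·1[live]) + genotype and block intercepts + Gaussian noise, all SDs
relative to the trait baseline (height 20 cm, biomass 0.55 g; nitrogen
effect +35%; residual SD 12%). The expected ME of genotype g in glasshouse
level e is me₀ + slope_e·z(g) with defaults me₀ = 0.05, slope_low = −0.12,
slope_high = +0.12 — opposite signs plant the adaptation signature.
Tillering is Bernoulli on a logistic predictor. Germination failure is
missing-completely-at-random at 27.25%, so 400 sown pots leave 291 plants in
expectation (~7.3 replicates per cell).

**What the generator does not emulate** — and hence what green tests do not
demonstrate about real data: read-level sequencing error and chimeras,
primer/amplification bias, compositional count dependence beyond the
Dirichlet-multinomial, taxonomic misclassification, phylogenetic signal in
effect sizes (effects are assigned to taxa independently of the simulated
tree, so weighted UniFrac carries no extra planted signal), temporal
dynamics, and any mechanistic soil chemistry. One structural artifact worth
knowing: because diazotroph occupancy is a *genotype-level* trait (the same
presence pattern in all replicates — deliberately, since downstream analyses
treat microbiome traits as conserved genotype traits), the nifH table's
PERMANOVA genotype R² is far above the 21–31% band; that band describes the
broad 16S community, where it is calibrated and tested.

## Numerical conventions and degenerate inputs

* P-value convention everywhere: (1 + #extreme)/(1 + n_perm), in (0, 1].
* Eigenvalue cutoffs: 1e-10 (relative) for PCoA axes, 1e-8 for dbMEM
  retention; orthonormality and inertia identities asserted at 1e-8.
* Forward-selection ties on P break toward larger pseudo-F; candidates with
  residual norm < 1e-10 are skipped.
* Saturated PERMANOVA designs, coincident dbMEM points, constant predictors,
  constant metrics, < 3 shared genotypes in the slope test, and non-positive
  sterile means are all explicit errors or flagged estimates, never silent.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage substreams from the run seed via `SeedSequence`, so
  bundles are byte-identical across repeat runs.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full study design
(40 genotypes × 5 replicates; 400 taxa for 16S, 40 for nifH; 10 × 2 × 2 × 10
trait experiment) for recovery and calibration checks, averaging over 20
independently seeded studies; null-calibration checks use 500 replicates of
a reduced null community (8 genotypes × 3 replicates, 60 taxa) and the full
trait design. These sizes are the package's chosen defaults for routine
verification; all are configurable.

## Known limitations

* The binomial Laplace fit can be optimistic for variance components near
  zero (a generic property of Laplace GLMMs); LRT χ² for fixed terms is
  accurate at these sample sizes but the variance estimates themselves are
  reported without uncertainty.
* Containment denominator df are a convention; with 10 genotypes the
  genotype-level F tests are approximate (calibration verified empirically
  under the null generator, not analytically).
* The slope-difference bootstrap propagates only the cell-mean uncertainty
  of ME; it conditions on the observed predictor values and assumes
  independence of perturbations between nitrogen environments.
* dbRDA marginal statistics are reported without permutation P-values
  (selection P-values come from the forward-selection tests).
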