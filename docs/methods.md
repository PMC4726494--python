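# Methods

This package reimplements, as tested code with synthetic ground truth, the
quantitative backbone of a karyotype-stability study of clonal hybrid
spined loaches (*Cobitis*): additive karyotype arithmetic with GISH-based
parental-set assignment, and a two-step molecular dating chain that puts
clone ages (mitochondrial) and speciation times (nuclear) on one absolute
time scale.

## Karyotype arithmetic and GISH assignment

Three sexual species contribute haploid genomes, abbreviated E
(*C. elongatoides*, n = 25), T (*C. taenia*, n = 24) and N (*C. tanaitica*,
n = 25); hybrids are written as strings of those letters (EEN = triploid
with two E sets and one N set).  Each haploid complement is a count vector
over the four Levan centromere classes (metacentric, submetacentric,
subtelocentric, acrocentric).  Under strict clonal transmission a hybrid's
karyotype is the category-wise sum of its letters' haploid complements;
`verify_additivity` reports observed − expected per category.  Categories
are taken as given labels: arm-ratio measurement from chromosome images is
out of scope, as is any image processing.

GISH paints each chromosome with two whole-genome probes; the classifier
reduces a chromosome to its green-channel share of total signal and
assigns it to the green-probed set iff that share exceeds a threshold
(default 0.5).  Exact threshold hits, or values inside a configurable dead
zone ±ε (default ε = 0), are reported as ambiguous rather than
force-assigned — balanced signal is treated as non-specific hybridization
noise, never as evidence of recombination.  How signal ratio is
operationally quantified per chromosome is an abstraction of this package;
the synthetic generator draws it from Beta distributions (mean 0.9/0.1,
concentration 50 by default) around each true origin.

The reference karyotype table and the study-design (cohort) table ship as
TSV fixtures so other taxa can reuse the modules; printed "total" rows and
columns are never trusted — loaders drop them and aggregation recomputes
them.  Entries printed as "-" parse as zero for sums but are retained as
absent in the records.

## Clone age: coalescent TMRCA by sequential importance sampling

The age of a clonal matriline is the TMRCA of its mtDNA haplotypes under
the neutral Kingman coalescent with infinite-sites mutation.  Time is in
coalescent units of N_f generations (N_f = female effective size; the
locus is haploid and maternal), so each lineage pair coalesces at rate 1
and each lineage mutates at rate θ/2 with θ = 2 N_f μ, μ the per-locus
per-generation mutation rate.  Data are reduced to a binary site matrix
over distinct haplotypes with multiplicities; a four-gamete check (and a
stricter rooted-perfect-phylogeny check) guards the infinite-sites
assumption.

The sample probability satisfies the classic backward recursion over the
most recent event — a coalescence of two identical sequences
(coefficient n_k(n_k − 1)) or removal of the youngest mutation, which is
necessarily a site private to a singleton haplotype (coefficient θ).
The sequential importance sampler proposes events with probability
proportional to those coefficients and multiplies the particle weight by
Σ coefficients / (n(n − 1 + θ)) per step.  Design choices:

* **Likelihood convention.**  The target is the probability of the
  row-labelled sample with sites identified up to relabelling.  The
  θ-profile maximum and all posterior quantities are invariant to the
  constant multinomial factor separating this from the unlabelled-data
  probability.
* **Driving value.**  Histories are simulated once at θ₀ = Watterson's
  estimate and re-weighted analytically across the whole θ grid (common
  random histories), so the profile is a smooth function of θ; the grid
  maximum is refined by bounded golden-section search.  The default grid
  is log-spaced over a factor of 100 around θ₀ (21 points).
* **TMRCA posterior.**  Holding times between events are drawn at their
  unconditional exponential rates k(k − 1 + θ)/2; the weighted particle
  heights give the posterior mean and a weighted 2.5/97.5-percentile
  interval (cumulative-weight inversion, ties to the midpoint).
* **θ propagation.**  By default the TMRCA interval conditions on the
  plug-in θ̂ (only the TMRCA uncertainty is propagated into years).  A
  joint mode draws θ from the normalized profile likelihood over its grid
  and pools conditional TMRCA runs; the pooled (TMRCA, θ) pairs travel
  together into the year conversion.  The end-to-end coverage property is
  tested in the joint mode; the plug-in mode under-covers when the sample
  carries few segregating sites, because θ̂ error then dominates.
* **Default particle count** is 10⁵ per run (configurable; the validation
  studies use 3–20 × 10³ per replicate and state so below).  Griffiths–
  Tavaré proposals have heavy-tailed weights at n ≈ 30, so reported
  effective sample sizes of the importance weights are typically a few
  percent of the particle count; all interval checks are calibrated
  empirically by the coverage studies rather than by nominal ESS.
* **Ewens cross-check.**  The infinite-alleles ML θ (from the number of
  distinct haplotypes) provides a fast independent estimator; tests check
  order-of-magnitude agreement with the SIS profile on simulated data.

## Chronogram: penalized-likelihood dating

A rooted phylogram with branch lengths in substitutions/site is converted
to an ultrametric chronogram by maximizing a Poisson log-likelihood of
per-branch substitution counts x_j = b_j·L with mean r_j·t_j·L, minus
λ × roughness (squared rate difference between each branch and its parent
branch, plus the variance of the root's child rates).  Counts are kept
continuous with a log-gamma generalized factorial; zero-length input
branches are floored at 10⁻⁸ substitutions/site.  One fixed calibration
age at the MRCA of a named tip set (typically the root) sets the scale.

* **Optimization.**  Node ages are parameterized by per-node depth
  fractions (logit scale), which enforces parent > child and pins the
  calibrated node exactly; rates are log-transformed.  A single
  quasi-Newton (L-BFGS-B) run over the joint vector, with 10 seeded random
  restarts by default, replaces age/rate block alternation — empirically
  more robust on small trees.  Non-convergence is reported in the result's
  diagnostics, never silently.  Fits can be warm-started from a related
  fit's ages and rates keyed by leaf set.
* **Rescaling.**  Multiplying the calibration age by c multiplies ages by
  c and divides rates by c exactly when λ is rescaled to λc² (the
  roughness penalty is quadratic in rates); the property test does so.
* **Cross-validation.**  λ is chosen by leave-one-tip-out CV on a default
  grid 10⁻³…10³ in half-decade steps.  The default score is the
  *stability* criterion D² = Σ_nodes (age_full − age_pruned)²/age_full
  over internal nodes shared by the full and tip-pruned fits — the
  criterion used by `chronopl` in the R package ape, whose behaviour this
  module mirrors.  Pruned fits are warm-started from the full fit so D²
  measures data-driven shifts, not optimizer jitter.  A prediction-based
  score (expected substitutions of the removed terminal branch from the
  attachment node's rate and age, χ²-style, denominator floored at half a
  substitution) is available as `score="prediction"`.  Selection takes the
  largest λ within 10% (relative) plus 1% of the calibration age
  (absolute) of the minimum score — a one-standard-error-style parsimony
  rule for the plateaus the CV curve shows on clock-like data.  At the
  committed problem size (8 tips, L = 1140) single-dataset selections
  remain noisy; the validation studies therefore aggregate selections over
  five independent datasets per rate regime and compare medians.
* **Lineage-averaged rate.**  The mean substitution rate over the spanning
  subtree from a tip set's MRCA to the tips (unweighted over branches); a
  `terminal_only` switch averages the terminal branches instead.  The two
  conventions answer slightly different questions (whole-lineage history
  vs recent rates), so both are exposed.

## Speciation times: multispecies coalescent MCMC

Divergence times of the sexual species are estimated on the fixed topology
((T,N),E) from multilocus nuclear alignments: parameters are τ_TN < τ_TNE
(expected substitutions/site) and five population sizes θ = 4 N_e μ (T, N,
E, TN, TNE).  Gene trees coalesce pairwise at rate 2/θ inside each
species-tree branch; sequences follow JC69 (uniform base frequencies, no
within-locus rate heterogeneity — among-locus variation is carried
entirely by fixed per-locus rate scalars, estimated as each locus's mean
JC-corrected ingroup–outgroup distance over the grand mean, so scalars
average to one; an uncorrected p-distance switch exists).

The sampler is Metropolis-within-Gibbs: per-locus gene-tree node-time
slides (uniform in the local window; multiplicative for the root) and
narrow-exchange topology moves; θ multiplier updates (cheap, via cached
per-population sufficient statistics of the coalescent density); and τ
"rubber-band" moves that remap the coalescent times contained in the
affected populations (proportional scaling below the moved boundary,
linear interpolation inside straddling populations, rigid shift above the
root divergence) with the exact Jacobian; τ_TNE uses a multiplier proposal
so the move stays reversible at the τ_TN bound.  Priors default to
Gamma(2, 2/mean) on τ_TNE and each θ with τ_TN/τ_TNE uniform on (0,1);
hyper-means come from data heuristics (within-species diversity for θ̄,
half the deepest between-species distance for τ̄), all overridable.
Chains default to 6000 sweeps, 25% burn-in, thinning to ≤ 2000 samples,
with step sizes Robbins–Monro-tuned toward ~30% acceptance during burn-in
only.  Effective sample sizes (Geyer initial-positive-sequence) below a
floor are reported as warnings, never swallowed.  Prior-only runs (empty
alignments) reproduce the prior — the standard correctness check for the
move set — and a 20-replicate study at the committed size (9 loci, 2
haplotypes/species, 500 sites) gives 19/20 coverage of both true τ values
by the 95% posterior intervals.  The validation chains use 4000 sweeps
with one slide per locus per sweep; coverage matched the heavier setting.
Core support is 1–4 haplotypes per species per locus; species-tree search,
migration and >3 ingroup species are out of scope.

## Absolute-time conversion

Rates are carried per MYA internally; the single 10⁶ years/MY constant
lives in one module.  Clone age: μ_gen = rate·10⁻⁶·L·g per locus per
generation, N_f = θ/(2 μ_gen), t = TMRCA·N_f·g years, with the interval
endpoints mapped through the same monotone transform (or the pooled joint
draws in θ-propagation mode).  The mitochondrial locus length defaults to
L = 1140 (canonical cytochrome-b length) and is prominently configurable;
generation time defaults to two years.  Speciation times scale linearly:
τ_abs = τ/τ_outgroup-split × outgroup age, applied per posterior sample.

## What the generators emulate — and what they do not

Every simulator is a pure function of (parameters, seed) and ships a truth
record.  The infinite-sites generator reproduces the neutral-coalescent
assumptions of the estimator exactly (panmixia, constant N_f, no
recombination or selection), so recovery tests validate the inference
machinery, not the biological adequacy of those assumptions for real
clonal lineages.  The MSC generator likewise matches the estimator's model
(no migration, no within-locus rate variation); real nuclear loci violate
both in ways the coverage study cannot detect.  The phylogram generator
adds Poisson substitution noise to a random ultrametric tree under a
strict clock or a log-normal rate walk (each child edge's log-rate = the
parent's + N(0, σ²)); it does not emulate alignment error, saturation or
model misspecification.  The GISH generator draws signal fractions from
Beta mixtures and cannot stand in for real fluorescence artefacts.
Consequently, green tests here demonstrate internal consistency and
statistical calibration under the stated models, not field performance.

## Validation problem sizes

Chosen once for the validation studies and used throughout tests and the
acceptance script: clonal samples n = 30 at θ = 1.156; SIS profiles at
8–20 × 10³ particles per replicate; chronograms with 8 tips, root 16 MYA,
rate 0.0065/site/MYA, L = 1140; λ-selection contrasts at σ = 0 vs σ = 1.5
over five datasets per regime; MSC studies with 9 loci, 2
haplotypes/species, 500 sites, scalars spanning 0.6–1.4; 20 replicates for
every coverage or recovery claim.

## Known limitations

* The GT proposal's weight degeneracy grows quickly with sample size and
  segregating sites; beyond n ≈ 50 a better proposal family would be
  needed.
* CV smoothing selection at 8 tips is noise-limited; single-dataset
  selections should not be over-interpreted (aggregate as the tests do).
* The MSC sampler fixes the species topology and the per-locus scalars;
  scalar estimation error is not propagated into the τ posteriors.
* All quantitative claims in this package are about synthetic data with
  known truth; applying the chain to real mitochondrial or nuclear
  datasets requires supplying those alignments and calibrations as
  inputs.
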