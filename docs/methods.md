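# Methods

## Data model

The substrate of all community typing is a samples × species matrix of
relative abundances (`AbundanceTable`): non-negative rows summing to 1
within 1e-6. Rows whose sums deviate by at most 0.05 are renormalized with a
warning (sequencing pipelines often emit percentages summing to 99.9); a
larger deviation is rejected as a count table passed where fractions were
expected.

The Dirichlet-multinomial likelihood is defined on counts, so fractions are
scaled to integer pseudo-counts at a uniform pseudo-depth `T` (default
10,000) by entry-wise rounding (`to_counts`). A uniform depth removes
depth-driven differences in overdispersion between samples; after
renormalization each fraction is recovered within the rounding bound
`(1/2 + S/2)/(T − S/2)` for S species. Depths below 100 are rejected as too
coarse for mixture fitting.

Sample metadata carries participant id, day of life and birth mode; nominal
timepoint labels are derived from half-open day-of-life windows, by default
day4 = [3, 6), day7 = [6, 14), day21 = [14, 35), infancy = [180, 395) days
(configurable). Missing covariate values are retained as an explicit
`missing` level and dropped listwise only inside model fitting.

## Divergence and diversity

All information-theoretic quantities are in nats. Shannon diversity is
`H = −Σ p ln p` with `0 ln 0 ≡ 0`. The Jensen–Shannon divergence uses the
same conventions and needs no pseudocount (the mixture `M` is positive
wherever either argument is); it is bounded by ln 2 and computed exactly,
with tiny negative rounding clipped at 0. Clustering uses raw JSD by
default; `sqrt=True` gives the metric square root, which is what PCoA
prefers (raw JSD can produce negative eigenvalues, which PCoA reports and
drops).

## PAM typing

`pam_cluster` is the classical BUILD + SWAP k-medoids: greedy BUILD
seeding, then repeated application of the best strictly-improving
(medoid, non-medoid) exchange, with every tie broken to the lowest sample
index and the total cost asserted non-increasing within each SWAP phase.
A single deterministic start can end in a swap-local minimum even on
instances small enough to verify exhaustively, so a handful of seeded random
starts (default 5 total) are run and the lowest-cost local minimum kept;
the result is deterministic given the seed. On small instances (n ≤ 8,
k ≤ 3) this reproduces the exhaustive k-medoids optimum in the test suite.

The number of clusters is chosen by the Calinski–Harabasz index computed
directly from the distance matrix via the pairwise-squared-distance
dispersion identity `W = Σ_c (1/n_c) Σ_{i<j∈c} d²`, `T = (1/n) Σ_{i<j} d²`,
`B = T − W`; this avoids committing to any embedding dimensionality and
coincides exactly with the classical centroid-based CH when the distances
are Euclidean. `W = 0` (duplicated points) maps to a +inf sentinel.
Silhouette widths use the standard `(b − a)/max(a, b)` with singletons
scored 0.

## DMM typing

The mixture likelihood is `Σ_k π_k DM(x | α_k)` with the
Dirichlet-multinomial log-pmf assembled from log-gamma terms. EM details:

- **Initialization** — k-means++ (10 restarts, seeded) on the relative
  abundances gives hard labels, softened to responsibilities 0.95/0.05;
  component α start from responsibility-weighted mean fractions at
  concentration 50 and are refined immediately.
- **M-step** — mixture weights are mean responsibilities; each α_k is
  updated by the responsibility-weighted fixed-point iteration (the
  digamma-ratio form), at most 100 inner iterations to relative tolerance
  1e-6, floored at 1e-10 to keep the parameter space open.
- **Convergence** — the observed-data log-likelihood is asserted
  non-decreasing at every iteration (a violation beyond 1e-8 aborts the
  run) and EM stops when it improves by less than 1e-4 nats (at most 500
  iterations). A component collapsing below weight 1e-8 triggers a bounded
  number of restarts from perturbed seeds.

**Model evidence.** The number of components is chosen by a Laplace
approximation to the negative log model evidence, evaluated in the
unconstrained parametrization (log α entrywise; softmax logits for the
weights with the last pinned at 0, so `d = KS + K − 1` free parameters):

    score = −[ loglik + ln p(θ̂) + (d/2) ln 2π − ½ ln det H ]

where `H` is the Hessian of the negative log-posterior at the optimum. The
likelihood Hessian is assembled by central finite differences of the
analytic gradient (fixed step 1e-4), which was itself verified against a
scalar finite-difference oracle. The evidence is computed under independent
weak Gaussian priors N(0, 3²) on the unconstrained parameters. The prior is
not decorative: a weakly occupied extra component leaves the likelihood
almost flat along its parameters, so a prior-free Laplace penalty for those
directions is nearly zero and model selection degenerates into noise between
adjacent K (measured on planted three-component data: ~27 nats of penalty
per extra component against genuine maximum-likelihood gains of a similar
size). The weak prior floors the curvature at 1/9 per direction and adds the
prior density at the optimum, after which the score has a clear minimum at
the planted K. The prior scale 3 (in log-α / logit units) comfortably covers
the plausible magnitude range of microbiome Dirichlet parameters; directions whose posterior curvature falls at or below the prior's
(label-symmetry ridges of near-duplicate components) are treated as
prior-dominated — their eigenvalues are floored at `1/sd²`, so they
contribute zero net evidence — and a non-finite determinant falls back to a
BIC-style penalty with a warning. Component drivers are ranked by expected relative abundance with
ties broken in species-id order.

## Ordination, envfit and concordance

PCoA is classical Gower double-centring of `−½ d²` with an eigenvalue
decomposition; negative eigenvalues (expected for raw JSD) are reported but
excluded both from the returned axes and from the variance-explained
denominator. No Lingoes/Cailliez correction is applied by default.

Envfit-style attribution regresses each species' abundance vector (with
intercept) on the first two ordination axes; `R²` is the squared multiple
correlation, and the permutation p-value is `(1 + #{R²_perm ≥ R²_obs}) /
(1 + n_perm)` with the species vector permuted across samples (999
permutations by default, seeded), followed by Benjamini–Hochberg correction
across species. Constant vectors get `R² = 0, p = 1` by convention. Cluster
naming assigns each cluster the highest-ranked driver species whose mean
abundance peaks in it.

Cramér's V between two assignments is `sqrt(χ² / (n (min(r,c) − 1)))` from
the contingency table without continuity correction, defined as 0 when
either labeling is constant.

## Longitudinal dynamics

The week-1 state is the day-4 state when sampled, else day 7. Transition
tables are exact cross-tabulations over participants observed at both
timepoints (exclusions counted and reported); stratified tables partition
the pooled one by construction. Retention tests compare retained/switched
2×2 tables per state pair by chi-square without continuity correction
(expected cells below 1 are flagged but still tested), BH-corrected across
pairs. Carriage is relative abundance ≥ 0.1 % — the boundary is inclusive
by decision, stated so the tests can be exact. Wilcoxon signed-rank tests
are exact for n ≤ 25 pairs via a dynamic program over doubled midranks
(this handles ties, which the textbook exact tables do not) and use the
tie-corrected normal approximation above that; all-zero paired differences
give p = 1 with a warning.

## Risk-factor models

One-vs-rest outcomes are fitted by maximum-likelihood logistic regression
(Newton), with dummy coding against configurable reference levels. Perfect
separation is detected both by a singular-Hessian failure during fitting and
by any |β| > 15 after it, and reported as a distinct error; rank-deficient
designs are rejected with the offending columns named. Effect sizes are
odds ratios with Wald 95 % CIs; p-values are likelihood-ratio tests of the
exposure's levels jointly. The hierarchical framework orders variable
blocks distal→proximal; the adjusted model for an exposure contains every
variable of its own and all earlier blocks, dropping (with a log note)
non-exposure variables that exceed 15 % missingness, and can additionally
adjust for the week-1 state as a sensitivity analysis.

## Functional genotyping

QC thresholds are inclusive at the boundary. HMO rules are shipped as a
versioned TSV (alternatives `|`-separated, co-required genes `+`-joined):
2′-FL (GH95 or GH29; transporters FL1_Blon0341-0343 or FL2_Blon2202-2204),
lactose (GH2; LacS), fucose (FumC+FumD+FumE+FumF+FumG; FucP), LNT (GH42 or
GH136; GltABC), LNnT (GH20; Bbr_1554), LNB (GH112; GltABC). All substrates
default to requiring enzyme *and* transporter except 2′-FL, which defaults
to enzyme-only: the GH95/GH29 genotype occurs in strains with no known
2′-FL importer that nevertheless grow on 2′-FL, so the enzyme defines the
genotype while the strict joint mode remains selectable. Gene identifiers
match exactly after case-folding; locus-tag-style identifiers are opaque
tokens. Burden is the count of distinct AMR plus virulence genes per
genome. ESBL carriage requires both a family prefix (CTX-M/OXA/SHV/TEM) and
the curated ESBL class label on the hit; unknown prefixes are tallied and
ignored.

## Synthetic data: what it emulates and what it does not

The generators plant the structure the pipeline is designed to detect, at
the cohort-scale figures used throughout the examples: state mix
17.6/43.4/38.9 % (BB/EF/BL), mean driver dominance 56.5/21.7/27.2 %,
week-1→week-3 retention 0.92/0.29/0.89 under vaginal delivery (caesarean
defaults 0.80/0.39/0.65; the BB value is a realistic choice where no figure
is fixed), per-birth-mode initial state mixes from the longitudinal subgroup
counts (VD 26/39/75, CS 26/114/26), and GH95 frequency 0.976 in *B. breve*
vs 0.049 in *B. longum*. The dominance spec maps to Dirichlet parameters by
`α_driver = c·m` and the remainder uniform at `c(1−m)/(S−1)` with
concentration `c = 50`, so the mean dominant abundance equals `m` by
construction with realistic dispersion. Off-diagonal transition mass is
split between the other states in proportion to their initial prevalence in
the stratum. In the confounded covariate scenario a distal maternal
confounder raises both the exposure probability and the outcome log-odds,
so the crude OR overstates the planted conditional OR.

The generators emulate mixture structure, Markov state dynamics, logistic
covariate links and per-species gene frequencies. They do **not** emulate
compositional artefacts of real profilers (ragged sequencing depth,
detection limits, taxonomic misassignment), within-state phylogenetic
correlation between species, time-varying abundance within a state, or
linkage between gene families on real genomes (genes are sampled
independently). Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to real-world
profiling noise.

## Problem sizes and tolerances in the test suite

Recovery suites run the typing routes on 20 seeded cohorts of n = 600
samples × 30 species (scanning K = 1–5 for DMM and k = 2–8 for PAM),
retention recovery on 500 participants, and odds-ratio recovery at
n = 3,000 with 200-replicate CI coverage — sizes chosen to make the planted
signals comfortably estimable while keeping the full suite fast. Acceptance
bands follow from sampling error at those sizes: mixture weights within
±0.05 of planted after label matching, retention within ±0.05, planted
OR 2.3 recovered within [1.9, 2.8] (20-seed median), CI coverage within
93–97 %.

## Known limitations

- The DMM fitter is EM with deterministic seeding, not variational or MCMC;
  multimodality is addressed only through the k-means++ restarts.
- The Laplace score's finite-difference Hessian costs O(d) gradient
  evaluations; for very large K·S a block-diagonal approximation would be
  preferable.
- PAM targets cohorts up to a few thousand samples; no CLARA-style
  subsampling is provided.
- No imputation of missing timepoints and no multi-state Markov model
  fitting: transition analyses report empirical proportions only.
- The three one-vs-rest logistic models are fitted independently; no
  multinomial joint model is provided.
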