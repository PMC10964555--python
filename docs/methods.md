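# Methods

This note records the models behind each module, the defaults that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Phylogenies and phylogenetic metrics

Trees are handled as rooted dendropy trees wrapped in a `PhyloTree` that
caches an edge table (per edge: length and descendant tip set) and the
patristic distance matrix derived from it. Faith PD is the summed length
of edges with at least one present descendant, root path included by
default (`include_root=False` restricts to the MRCA subtree). Both
UniFrac variants are sums over the edge table: unweighted is unshared
covered length over total covered length; weighted is the normalized
variant Σ b|p_A − p_B| / Σ b(p_A + p_B), bounded in [0, 1]. Both match
scikit-bio to 1e-10 on random instances (tested).

MNTD is the mean (optionally abundance-weighted) distance from each
present tip to its nearest present neighbour. NTI uses the sign
convention NTI = −SES(MNTD), so clustering is positive; the null
shuffles tip labels on the patristic matrix ("taxa labels"
randomization), with `sd(null)` computed with one delta degree of
freedom. An `exhaustive=True` mode enumerates all tip permutations and
is the basis of the exact-null tests. Degenerate nulls (zero spread)
raise rather than return a sign.

βMNTD symmetrizes the two directed nearest-taxon means and defaults to
abundance weighting. βNTI uses one tip permutation per null iteration
shared across all pairs, so each iteration yields an internally
consistent null βMNTD matrix; 1,000 iterations by default, reducible for
large designs. Identical samples are inherently degenerate under this
null (shared taxa are their own nearest neighbours at distance zero in
both observed and null), so such pairs are flagged undefined instead of
being forced into a class.

## Permutation statistics

All permutation p-values use (1 + exceedances)/(1 + permutations).
PERMANOVA computes pseudo-F from tr(HG), with G the Gower-centered
−½D² matrix and H the projection onto centered (dummy-coded)
explanatory variables; free permutation of sample labels. Defaults:
10,000 permutations for the host-community ordination test, 999
elsewhere. PERMDISP keeps negative PCoA eigenvalues as imaginary axes
and subtracts their squared contribution from distances to group
centroids (clipped at zero), then permutes group labels over the fixed
distances. db-RDA instead applies a Lingoes additive constant so all
axes are real, regresses the coordinates on constraints, and reports
constrained inertia, R² and adjusted R²; the two negative-eigenvalue
conventions are deliberate and tested separately. With a single binary
constraint and Euclidean input the db-RDA pseudo-F equals the PERMANOVA
F (tested to 1e-9).

Forward selection is greedy on adjusted R² with two stopping rules: the
candidate's conditional permutation p must be ≤ 0.05, and its adjusted
R² must not exceed the full model's. Because adjusted R² is unbiased
under pure noise, a sub-model lacking only noise terms exceeds the full
model's value with probability near one half; a hard ceiling therefore
vetoes genuinely strong terms at a coin flip (vegan's `ordiR2step`
exhibits exactly this behaviour on a two-term scope). The ceiling here
carries a df-aware tolerance, 2(q_full − q_cand)(1 − adjR²)/n, sized to
absorb that fluctuation while still stopping selection-bias runaway; the
significance gate remains the primary stop.

## GLMs, model selection, differential abundance

`fit_glm` implements IRLS for Gaussian-identity and NB2-log models. The
NB dispersion α is profiled by maximizing the Cox–Reid adjusted
likelihood (ℓ − ½ log|XᵀWX|); plain ML dispersion is biased downward,
which in the Wald differential test inflated the null rejection rate to
~0.09 regardless of sample size. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with
k counting coefficients plus the scale (Gaussian) or dispersion (NB).
All-subsets selection fits every term subset that respects marginality
and ranks by AICc, ties broken by parameter count then term order.
Variance partitioning averages sequential explained deviance over all
term orderings (an explicit, testable stand-in for model-based
partitioning); fractions plus the residual sum to one.

Post-hoc comparisons are Wald tests on an explicit contrast matrix with
Benjamini–Hochberg adjustment — a studentized-range family correction is
deliberately not used because the biologically restricted contrast set
is not the full all-pairs family. The functional-redundancy ANCOVA fits
per-group least-squares slopes of functional on taxonomic richness
(slope < 1 ⇒ redundancy), tests slope heterogeneity by the interaction
F, and contrasts slopes pairwise; groups with fewer than three samples
or zero covariate variance are flagged, not guessed.

The differential-abundance test is a deliberately simplified
negative-binomial Wald procedure: +1 pseudocount, median-of-ratios size
factors, per-feature NB GLM with log size-factor offset, Wald statistics
referred to a t distribution with residual df (a small-sample correction
for the estimated dispersion), BH across all feature-coefficient tests.
There is no fold-change shrinkage and no empirical-Bayes sharing of
dispersions across features; equivalence with heavier reference tools is
not claimed. Null calibration: raw type-I 0.057 over 500 simulations at
n = 10 per group; power 1.0 at an 8-fold change with n = 20 per group
(both computed by the test suite and acceptance script).

## Amplicon filtering

Stage order is fixed: per-ASV thresholds → replicate confirmation →
taxonomy filter → rarefaction check → group-size filter → proportional
normalization. Thresholding discards counts at or below
max(T_CC, T_FA): the threshold equals the worst observed artifact, so
ties are treated as untrustworthy (a `strict` flag switches to
strictly-below). T_FA uses a ceiling to stay integer-conservative, and
the misassignment rate is the maximum of the configured default (1e-4)
and the rate estimated from internal-control leakage. Thresholds are
computed on pooled replicates; replicate confirmation is applied after
thresholding each replicate separately (the stricter order). The
rarefaction plateau criterion — expected new features in the next 1,000
reads below 1.0, from the multinomial extrapolation
Σ(1−p)^N(1−(1−p)^1000) — supplies a concrete cutoff where practice
usually relies on visual inspection; curves themselves use the exact
hypergeometric expectation. Dead-on-trap individuals and outlier species
are removed via metadata flags since the underlying biology is not
computable from counts.

## The synthetic generator

Every generator is a pure function of its arguments including the seed.

* **Trees**: Yule (pure birth) with exponential waiting times, rescaled
  to unit root-to-tip depth — the simplest shape with strictly positive
  branch lengths.
* **Filtering**: environmental filtering through a phylogenetically
  conserved habitat trait, modeled in its strong-signal limit: the
  optimum is a focal lineage and the admissible pool is the
  n_tips/strength tips nearest to it; each sample admits pool members
  independently at a rate targeting the expected richness (default 15),
  with uniform multinomial abundances. A finite-signal Brownian trait
  window was tried first and rejected: trait windows admit convergent
  tips from many clades, and extreme optima concentrate abundance on
  shared taxa, which contribute zero to both observed and null βMNTD —
  under that model the generator could not produce the homogeneous
  selection signal the filtering scenario is supposed to embody.
  The recorded ground-truth trait is the patristic distance to the
  optimal lineage.
* **Competition**: sequential admission with probability proportional to
  the minimum patristic distance to the admitted set raised to
  `strength`; strength 0 degenerates to uniform admission.
* **Neutral**: a fixed log-series metacommunity (x = 0.98, shuffled onto
  tips) sampled multinomially. `strength` adds a drift stage: each
  sample is a local community of depth/strength individuals drawn from
  the metacommunity and then sequenced to full depth. strength ≤ 1 is
  plain metacommunity sampling (nearly identical samples at realistic
  depth); large strength produces the idiosyncratic between-host
  divergence that the Anna Karenina scenario requires, while leaving
  phylogenetic structure neutral.
* **Functions**: each ASV is assigned one module uniformly among
  min(n_function_modules, n_tips/redundancy) modules, so mean module
  occupancy equals the redundancy parameter; redundancy ≤ 1 is the
  identity map.
* **Sequencing**: two independent technical replicates at
  Poisson-distributed depth; kitome contamination injected into every
  sample and negative control at contamination_rate × depth (default
  0.002); per-feature binomial misassignment of run-total reads to
  random wrong samples (default rate 1e-4, calibrated within 3 SE in
  tests); one internal-control feature confined to its own sample before
  misassignment.
* **Trapping**: Poisson captures per site × species from an intensity
  profile whose default includes rural-only, urban-only and shared
  species, capped at traps × nights.

The generator does **not** emulate read-level errors, chimeras, PCR or
primer bias, compositional correlations between taxa, overdispersed
(lognormal) abundance noise, or phylogenetic signal in function
assignment. Passing the recovery tests therefore shows the inference
chain is correct under its stated model, not that it is robust to every
artifact of real amplicon data.

**Standard design** (used by the end-to-end tests and the acceptance
script): three processes × two redundancy levels (1 and 5), 15 samples
per group, 200 tips, depth 2,000, expected richness 15; filtering
strength 5 (40-tip pool), competition strength 3, neutral drift
strength 100 (local communities of ~20 individuals). These sizes keep a
full pipeline run near ten seconds while leaving each recovery signal
far from its threshold.

## Decision tree

Per species-site group: step 1 (flexibility) asks whether the group's
composition differs from at least one other group (pairwise PERMANOVA,
BH-adjusted p ≤ 0.05; the global tests are used when only two groups
exist). Step 2 flags functional redundancy (slope < 1) and classifies
phylogenetic dispersion from the group's mean NTI against ±2. Step 3
takes the majority βNTI label over within-group pairs (ties conservatively
stochastic) and compares the group's mean distance-to-centroid with the
average over groups. Step 4 lists BH-significant differentially abundant
functions. The Anna Karenina dysbiosis flag requires stochastic
assembly *and* high dispersion *and* a neutral step-2 verdict — the last
condition keeps deterministically overdispersed (competition-like)
groups from being called dysbiotic, and strictly strengthens the
invariant that the flag implies stochastic-and-dispersed. Overall:
`stable` when not flexible, `dysbiosis_risk` when the flag fires,
`adaptive_flexibility` otherwise. These combination rules are explicit
configuration of this package; no claim is made that any field study
combined its steps this way.

## Numerical choices and limitations

α = 0.05 throughout; BH within each family of tests. Permutation
defaults follow the module docstrings; every stochastic routine takes a
seed and is reproducible. Distance matrices are validated for symmetry
and zero diagonal at 1e-10. The chi-square of process counts drops
groups with expected cell counts below one, re-pooling the rest. The NB
IRLS clips the linear predictor at ±30 and raises on non-convergence
after 60 iterations. Known limitations: NTI/βNTI inherit the usual
power ceiling of nearest-taxon statistics at high richness-to-pool
ratios; the dispersion-high rule is relative to the groups in the
design, so a design in which every group is equally dispersed cannot
raise the dysbiosis flag; and the simplified differential-abundance test
should not be expected to reproduce shrinkage-based tools feature for
feature.
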