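# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gslab`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The two trial designs and what the simulator emulates

The package targets the situation of mid-rotation conifer progeny trials:

* **Full-sib design** — a partial diallel over 54 parents yielding 37
  crossed families, ~1,330 offspring planted over 3 sites (~440/site).
  Parents are reused across crosses, so families are connected by
  half-relative ties and the effective population size is small. Parent
  pairs are drawn by a Polya urn (draw probability ∝ times-used +
  `urn_alpha`); the default `urn_alpha = 1.1` was calibrated once, at
  design time, so the status number of the sampled offspring comes out
  near 21, the regime of an intensively managed elite population.
* **Open-pollinated half-sib design** — 25 seed parents, ~1,125 offspring
  over 3 sites. Each offspring's pollen parent is drawn uniformly from a
  pollen cloud of 500 unrelated founders and recorded as *unknown* in the
  pedigree (the simulator keeps the realized identity for truth-based
  checks). With 25 dams plus a diffuse pollen cloud the status number
  comes out near 90.

Status number is Ns = 0.5/Θ with group coancestry Θ = c′(A/2)c; for
unrelated non-inbred founders this reduces to 1/Σc²ᵢ. Contributions `c`
default to realized parental genome shares of the sampled offspring.

**Genome and markers.** A 12-chromosome, 2,000 cM map with uniformly
placed markers. Meiosis is Haldane (Poisson crossovers, no interference);
the bulk gamete sampler uses the equivalent independent-interval-parity
formulation (phase switches between adjacent markers are independent
Bernoulli draws at the Haldane recombination fraction), which has exactly
the same law at the marker loci and is fully vectorized. Founders are
simulated in **linkage equilibrium** with allele frequencies uniform on
[maf_min, 1−maf_min] (default 0.05): in these undomesticated, huge-genome
populations no usable population-wide marker–QTL LD exists, so everything
genomic prediction can exploit is *within-family* disequilibrium generated
by co-inheritance of large chromosome segments. Passing tests on this
generator therefore demonstrate relatedness-driven prediction, and say
nothing about LD-driven prediction in real data.

**Trait.** A polygenic additive trait from `n_qtl` (default 300) mapped
QTLs with N(0,1) raw effects, excluded from the observable SNP panel by
default so markers predict only through linkage/relatedness. Non-genetic
structure follows the trial models: site fixed effects (defaults
{0, +0.5σₑ, −0.5σₑ}), site×additive, block-within-site, site×family,
family and residual components. Default components
(σ²ₐ, σ²ₛₐ, σ²ₛᵣₑₚ, σ²ₛf, σ²f, σ²ₑ) = (2, 1, 0.5, 0.5, 0.5, 5.5) give a
mid-range full-sib h² ≈ 0.21, typical of height; the real trials' values
are not published.

**Variance calibration.** Every realized component vector (additive
values, site×additive draws, block, site×family, family, residual) is
centred and rescaled by a single constant so its empirical variance across
offspring equals the target exactly. Rationale: with only ~30 block and ~37
family levels, the realized variance of an uncalibrated draw scatters with
~25% relative SD, which would swamp any parameter-recovery assessment of
the estimator itself. The common rescaling leaves all correlation
structure (family blocks, within-site additive covariance) untouched; the
cost is that draws live on a fixed-variance shell rather than being
exactly Gaussian, which is immaterial at these sizes.

## The mixed models

Fixed effects are the overall mean and site (treatment coding). Random
terms and covariances:

| term | levels | covariance |
|---|---|---|
| additive `a` | all pedigree members | **A** σ²ₐ (tabular numerator matrix) |
| site×additive `sa` | one per tree | additive relationships within site, 0 across sites |
| block `s(rep)` | site × block | I σ²ₛᵣₑₚ |
| site×family `sf` | site × family (full-sib only) | I σ²ₛf |
| family `f` | family (full-sib only) | I σ²f |
| residual `e` | one per tree | I σ²ₑ |

The site×additive covariance deserves a note. Written casually it is
"~N(0, Iσ²ₛₐ)", but with each genotype grown at exactly one site an iid
per-tree term is *completely confounded* with the residual (both contribute
Iσ² to the phenotypic covariance), making the pair non-identifiable. The
standard identifiable formulation — the one ASReml-style trial analyses
actually fit — re-expresses the additive effect within each site with A
covariance and zero cross-site covariance (⊕ₛ A_s σ²ₛₐ), so that σ²ₛₐ is
carried by the *difference* between within-site and cross-site covariance
of relatives. `gslab` uses this structure in both the generator and the
model; `sa_structure="iid"` restores the literal identity reading for
experimentation.

**EM-REML.** Components are estimated by the classical EM-REML updates on
the observation-level covariance V = Σₖ σ²ₖ Bₖ + σ²ₑ I, which are monotone
in the REML log-likelihood. Plain EM is impractically slow on these
models (the a↔f likelihood ridge gives linear convergence rates beyond
0.999), so the fixed-point iteration is accelerated with SQUAREM squared
extrapolation under a likelihood safeguard with step backtracking: an
extrapolated point is accepted only if its REML log-likelihood has not
dropped, otherwise the step is halved toward the plain double-EM step and
ultimately replaced by it. The accepted-iterate log-likelihood path is
therefore non-decreasing exactly as for plain EM; `max_iter` counts
EM-map evaluations. Convergence is declared when one EM step changes every
component by less than `tol` (default 1e-6) relative to its size;
components pinned at the zero boundary are measured against a floor of
0.1% of the phenotypic variance so their numerical jitter cannot block
termination. Components are floored at 1e-8 to guard underflow.
Non-convergence returns the last iterate flagged provisional — on
near-flat ridges (e.g. sa vs sf in small trials) this is the honest
outcome: totals, heritability and EBVs are stable while the split wanders.

**Fast exact engine.** For the single-generation pedigrees of these trials
every term kernel factors exactly as diagonal + sparse low rank:
A₍obs₎ = 0.5 I + 0.25 MM′ with M the (0/1) known-parent incidence (entries
0.5 in the factor), analogously per site for sa, and Bₖ = ZZ′ for the
indicator terms. The REML engine then evaluates each EM iteration with
Woodbury identities in r×r algebra (r ≈ 400 at n ≈ 2,000; ~15 ms per
iteration against ~0.5 s for the dense path). The factorization is
validated elementwise against the dense kernels at construction and the
engine is only used when it is exact; loaded multi-generation pedigrees
fall back to the dense path automatically. Unit and property tests assert
agreement of the two paths to 1e-8.

**Starting values** come from an ANOVA-style moment initializer: pairwise
site-centred products are averaged within relationship classes
(relationship 0.5 / 0.25 × same/different site, plus shared block) and
solved for the components by their class expectations, clamped to
[0.02, 2]×var(y).

**BLUP.** With components fixed, Henderson's mixed-model equations are
assembled (λₖ Gₖ⁻¹ added to each random block) and solved by dense
Cholesky; EBVs exist for all pedigree members including unphenotyped
parents. Identity with direct GLS on the same covariance is asserted to
1e-8 on toy models.

**ABLUP cross-validation** masks each fold's phenotypes, re-solves the MME
at fixed components, and correlates the masked trees' pedigree-predicted
EBVs with their full-data EBVs. Note an inherent property of this
(standard) statistic: predicted and reference EBVs share family-mean
information, so it stays well above zero even for a heritability-zero
trait — it measures self-consistency of the pedigree prediction, not
accuracy against truth. The test suite therefore validates the null case
against the *true* simulated breeding values.

## RR-BLUP

Markers are coded 0/1/2 and column-mean centred (no per-marker variance
standardization — the ridge is homoscedastic, all effects shrunk
uniformly). The intercept is the training-response mean. λ defaults to a
one-dimensional spectral REML: eigendecompose the intercept-projected
kernel SKS (K = ZZ′), rotate, and maximize the profiled REML criterion
over δ = σ²ₑ/σ²g by bounded scalar search on log δ ∈ [−8, 8]; λ = δ
exactly. The solver takes the dual n×n path when m > n (ĝ =
Z′(ZZ′+λI)⁻¹(y−1μ)) and the primal otherwise; both are Cholesky
factorizations with a logged 1e-10 jitter retry, and λ = 0 is accepted
only with full-column-rank Z′Z (no pseudo-inverse limit). Equivalence of
primal and dual to 1e-8, monotone shrinkage in λ, and the classical
RR-BLUP/kernel-BLUP identity are asserted by tests.

## The marker-density experiment

Pipeline per design: simulate the trial → EM-REML + MME for offspring
EBVs → drop SNPs with heterozygote fraction ≥ 0.40 (the conifer
paralog-collapse filter) → for each SNP-set total in the grid draw
replicate random subsets (default 10) → replicated k-fold cross-validation
(default 10×10) of RR-BLUP per subset, λ re-estimated on each training
fold → summarise. Accuracy is the Pearson r(EBV, GEBV) of held-out trees,
pooled across sites. Per set-total statistics: the replicate-level mean
averages that subset's fold accuracies; reported mean/SD/SE are across
marker replicates (SE = SD/√reps). Degenerate folds (constant vectors)
are recorded as missing and excluded, never imputed.

The cross-validation engine works in the dual form on a per-subset raw
kernel ZZ′ computed once, with per-fold training-mean centring applied as
rank-one corrections — algebraically identical to explicitly re-centring
and refitting each fold (asserted against `fit_rrblup` in tests). This is
what makes grids to 50,000 markers with 100 CV fits per subset tractable.

Derived statistics: the **doubling factor** is the mean accuracy ratio
over exact (m, 2m) grid pairs; the **plateau threshold** is the smallest
set total whose mean accuracy reaches (1−rel_tol) of the grid maximum
(default rel_tol = 0.02, a numeric stand-in for what is usually judged by
eye); the **design ratio** is the elementwise full-sib/half-sib mean
accuracy ratio. The default grid {200, 500, 1,000, 2,500, 5,000, 10,000,
15,000, 25,000, 50,000} spans 0.1–25 markers/cM on a 2,000 cM map and
contains doubling pairs; tests and the acceptance script use the
scaled-down grid to 20,000 with 5 replicates and 5×5-fold CV on ~600-tree
trials, sizes chosen so the whole study runs in minutes on one CPU.

Seeding: one master seed spawns independent child streams for simulation,
marker sampling and CV partitions, so any stage reproduces in isolation
and the full experiment is bit-reproducible.

## Known limitations

* No standing LD, no selection, no dominance/epistasis, no missing
  genotypes, no genotyping error: the generator isolates the
  relatedness-vs-marker-density mechanism and is not a full breeding-cycle
  simulator. In particular, simulated accuracies speak to within-population,
  pedigree-driven prediction only.
* Pedigree REML in a single generation of phenotyped offspring separates
  additive from family variance only through cross-family parent-sharing
  covariances; within families, pedigree A is blind to Mendelian-sampling
  contrasts. The additive/family split is therefore weakly identified at
  the 37-family scale: per-dataset REML optima of σ²ₐ scatter widely and
  occasionally hit the zero boundary, which skews the paired family
  variance upward. Consequences are quantified in the test suite; the
  parameter-recovery check on 20 replicates recovers five of six
  components' means within 20% while the family variance can exceed it.
  With clonal replication or deeper pedigrees (out of scope) the split
  identifies cleanly.
* The sa/sf split in small full-sib trials is likewise near-flat; treat
  the individual interaction components as exploratory and their sum as
  reliable.
* `RelationshipMatrix` storage is dense; intended population sizes are a
  few thousand individuals. Henderson's sparse A⁻¹ rules are deliberately
  not implemented.
* Accuracy against non-deregressed EBVs is optimistic (shared family
  means); de-regression is deliberately out of scope, matching the
  methodology this package emulates.
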