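# gslab — genomic selection on pedigreed conifer progeny trials

`gslab` is a toolbox for studying **how many genome-wide markers genomic
selection (GS) actually needs** in species where linkage disequilibrium (LD)
cannot be resolved — conifers with ~20 Gbp genomes and ~2,000 cM maps. It
simulates the two classical trial designs of operational tree breeding
(crossed **full-sib** families with a small effective population size, and
open-pollinated **half-sib** families with a large one), estimates breeding
values with pedigree mixed models, predicts them from SNPs with
ridge-regression BLUP, and measures how prediction accuracy responds to
marker density under each pedigree structure.

It is aimed at quantitative geneticists and tree breeders who want a
self-contained, fully reproducible test bed for marker-density and
pedigree-structure questions: every analysis runs end to end on simulated
trials, with plain-text interchange formats for bringing in real tables.

## Models

**Pedigree BLUP (ABLUP).** Phenotypes from a multi-site progeny trial are
analysed with the individual-tree ("animal") model; for the full-sib design

    y = Xβ + Z₁a + Z₂sa + Z₃s(rep) + Z₄sf + Z₅f + e

with fixed mean and site effects β; additive genetic effects
a ~ N(0, **A**σ²ₐ) over the whole pedigree (**A** = numerator relationship
matrix, built by the tabular method); site×additive effects sa (additive
relationships within site, independent across sites); block-within-site
s(rep); site×family sf; family f; and residual e. The half-sib
(open-pollinated) model drops sf and f. Variance components are estimated
by EM-REML (monotone in the REML likelihood, with safeguarded SQUAREM
acceleration and an exact sparse low-rank fast path for single-generation
pedigrees), and breeding values solved from Henderson's mixed-model
equations. Narrow-sense heritability uses the trial formula
h² = σ²ₐ/(σ²ₐ + σ²ₛₐ + σ²ₛf + σ²f + σ²ₑ) (half-sib:
σ²ₐ/(σ²ₐ + σ²ₛₐ + σ²ₑ)).

**RR-BLUP.** Estimated breeding values are regressed on all centred SNP
dosages simultaneously, g ~ N(0, Iσ²g):

    y_EBV = 1μ + Zg + e,    ĝ = (Z′Z + λI)⁻¹Z′y,    λ = σ²ₑ/σ²g

with λ estimated by one-dimensional spectral REML on the marker kernel
ZZ′, and a dual n×n solver (identical to the primal formula to machine
precision) for p ≫ n. A genomic breeding value (GEBV) is the sum of an
individual's marker effects.

**Marker-density experiment.** SNP sets of increasing size are drawn at
random from the heterozygosity-filtered pool (< 0.40 heterozygote
fraction), each run through replicated k-fold cross-validation, and
accuracy r(EBV, GEBV) is summarised per SNP-set total with plateau,
doubling-factor, and full-/half-sib ratio statistics. Marker-requirement
calculators implement the 10·Ne·L rule and markers/cM bookkeeping, with
effective population size measured as the status number
Ns = 0.5 / group coancestry.

## Worked example

```python
import gslab as g

trial = g.simulate_trial("full-sib", seed=42, n_families=20,
                         offspring_per_family=24, n_markers=8_000,
                         n_qtl=200, n_parents=30)
pop = trial.population

model = g.PedigreeBLUP(trial.phenotypes, pop.pedigree_table(), kind="fullsib")
fit = model.fit(tol=1e-4, maxiter=1000)
print(fit.summary())

ebv = fit.ebv.loc[pop.offspring_ids]
idx, X = trial.panel_dosages()
keep = g.filter_snps_heterozygosity(X, 0.40)
cv = g.gs_cross_validate(ebv.to_numpy(), X[:, keep].astype(float),
                         folds=10, repeats=2, lambda_strategy="reml", seed=1)
print("RR-BLUP 10-fold CV accuracy r(EBV, GEBV): %.3f" % cv["accuracy"].mean())
```

prints

```
Pedigree BLUP (ABLUP) results
==================================
model kind        : fullsib
observations      : 480
pedigree members  : 510
REML converged    : False (1000 iterations)
REML log-likelihood: -763.546656
----------------------------------
sigma2_a     = 1.79032
sigma2_sa    = 0.332166
sigma2_srep  = 0.246084
sigma2_sf    = 0.760653
sigma2_f     = 0.00330361
sigma2_e     = 6.61741
heritability  = 0.1884
----------------------------------
fixed mean         = 9.64405
fixed site[S2]     = 2.1196
fixed site[S3]     = -1.3359
RR-BLUP 10-fold CV accuracy r(EBV, GEBV): 0.907
```

The additive variance (1.79 vs the generative 2.0) and heritability (0.19)
are recovered well at this small size. The `converged: False` flag is
honest: the likelihood is nearly flat between the confounded site×additive
and site×family terms, so their split (0.33 / 0.76 here) is
data-undetermined even though the total, the EBVs and h² are stable.
The cross-validated accuracy of 0.91 reflects the strong family structure:
with 20 full-sib families, 4,000 SNPs track relatedness essentially
perfectly — the central phenomenon this package exists to study.

At study scale (37 full-sib families on 3 sites, 46,000 simulated SNPs,
grid 200–20,000), `g.run_design_experiment` reproduces the canonical
findings: accuracy rises monotonically with marker number (0.77 at 200
SNPs to 0.84 at 20,000), saturates after a few thousand markers, and is
uniformly higher than the open-pollinated half-sib configuration (0.52 to
0.68), whose status number (~92 vs ~25) prices in its weaker family
signal.

A command-line umbrella is installed as `gslab` (subcommands `simulate`,
`amatrix`, `ne`, `ebv`, `ablup-cv`, `rrblup`, `gs-experiment`, `calc`);
run `gslab --help`.

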