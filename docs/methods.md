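# Methods

`aquagp` benchmarks genomic-prediction methods under the data regime of
aquaculture breeding programs: a two-generation factorial cross producing
tens to hundreds of full-sib families, roughly 750–1,500 phenotyped and
genotyped offspring, 11K–40K SNPs, and trait heritabilities between about
0.12 and 0.50. Everything below is computed by the package; the test suite
and `scripts/acceptance.py` re-derive every number quoted.

## Synthetic populations

**Mating design.** `simdata.make_factorial_pedigree` builds blocks of
dams × sires in which every within-block pair is a candidate full-sib
family; realized families are subsampled to a configured count and family
sizes are drawn from a configurable law. The default is a truncated
negative binomial (mean 12, dispersion 3), giving the strongly unequal
family sizes seen in practice (single fish up to ~50 per family); uniform
and constant laws are available for regimes like a 1–21-per-family cross.

**Founder genomes.** Marker allele frequencies are i.i.d. uniform on
[0.05, 0.5]. Two founder models are provided. With `n_ancestral=None`
founders are in linkage equilibrium, so all LD arises from the family
design. The default for whole-dataset simulation instead builds each
founder haplotype as a mosaic of a small pool of ancestral haplotypes
(default 30, segment-switch rate 0.05 per cM), emulating the long-range LD
of broodstock with small effective size. The second model is the package
default because, empirically, LE founders leave GBLUP with no
population-LD channel: its cross-validated correlation with true breeding
values then ties pedigree BLUP (0.744 vs 0.745 in our measurements), and
LD-based panel thinning cannot be accuracy-preserving — both at odds with
what marker-based prediction is for. Aquaculture populations are
precisely the small-Ne, long-range-LD regime.

**Gene drop.** Each offspring gamete recombines the parent's two
haplotypes with a Poisson(length/100) crossover count per chromosome,
uniform crossover positions, and no interference. Default map: 20
chromosomes × 100 cM, 12,000 markers on an even grid (positions also
exported as 1-based bp-like coordinates at 10 kb/cM).

**Traits.** Marker effects follow a four-class normal mixture with
variances (0, 1e-4, 1e-3, 1e-2)·σg² and default membership proportions
(0.95, 0.03, 0.015, 0.005) — deliberately the same family of architectures
the BayesR prior assumes. Effects are rescaled once so the realized
breeding-value variance equals the target σg², and the residual variance is
set from the realized var(BV) so that realized h² matches the target in
expectation. Fixed effects: batch-like factors (default a 3-level and a
2-level factor, effect SD 0.5) and one continuous covariate (slope 0 by
default). Missingness is i.i.d. dropout at a configurable rate.

What the generator does **not** model: genotyping error beyond missingness,
selection across generations, non-additive genetic variance, pedigree
errors, and sequence-level mutation. Passing tests therefore demonstrate
correctness of the estimators under an additive, correctly-specified world,
not robustness to those real-data pathologies; the real datasets' absolute
accuracies are not reproduced here and are not targets.

## Quality control and imputation

Filters follow standard SNP-array practice: samples with call rate < 0.90
first, then markers with MAF < 0.01, call rate < 0.90, or Hardy–Weinberg
exact-test p < 1e-7 (conditional exact test, chosen over chi-square for
robustness at small counts; validated against exhaustive enumeration for
all totals ≤ 50). Sample filtering precedes marker filtering because sample
removal changes marker statistics. Imputation is deliberately naive —
per-marker mean (2p̂, fractional dosages) or modal genotype — since
LD-aware imputation is a separate tool's job; fractional dosages are
accepted by all kernel builders, and BayesR rounds to integer dosages for
its design matrix.

## Relationship matrices

Pedigree A by the tabular method with founders unrelated and non-inbred.
Genomic kernels share one convention: Z = M − 2p per column,
K = Z D Z′ / Σ 2p_j(1−p_j), with allele frequencies estimated from the
current data. Monomorphic markers contribute nothing to the numerator and
are excluded from the denominator (they carry no information and would
otherwise only inflate the scale). Feature splits build G_f and G_r on
disjoint marker sets, each with its own denominator, so the 2pq-weighted
recombination of the two reproduces the full G exactly. Blending
G* = 0.95·G + 0.05·I guarantees invertibility inside the weighted-GBLUP
loop. Raw (unblended) G is used for plain GBLUP and GFBLUP.

## Mixed models

Variance components are estimated by average-information REML with
guaranteed-ascent EM fallback: an AI step is taken when, clipped into
bounds, it does not decrease the restricted likelihood; otherwise the EM
update θ ← θ + θ²(y′PKPy − tr(PK))/n is used. Starting values split half
the phenotypic variance equally across kernels; convergence is relative
parameter change < 1e-8 (bounded at [1e-8, 100]·var(y)) with a 200-iteration
cap and a flagged boundary return. Clipping the AI proposal rather than
rejecting it matters in practice: null traits then land on the σg² ≈ 0
boundary in under a dozen iterations instead of crawling by EM.

BLUP uses the covariance form ĝ_k = σ̂_k² K_k[·, train] V⁻¹(y − Xb̂) with
b̂ from GLS — algebraically identical to Henderson's mixed-model equations
(verified against a dense SNP-BLUP/MME oracle to 1e-6) but defined for
singular kernels. Fixed factors use reference-level dummy coding (first
observed level); any full-rank coding yields the same GEBVs. Records with
missing response or fixed effects are dropped with a logged count.

Cross-validation re-estimates variance components inside every training
fold (no leakage); the h² in the accuracy denominator is the one full-data
estimate per dataset, from the pedigree kernel when a pedigree exists and
from G otherwise.

## BayesR

Single-site Gibbs: per SNP a marginalized four-class membership draw, then
a conditional-normal effect (exactly zero in the null class); mixture
proportions from Dirichlet(1,1,1,1 + counts); flat priors on fixed effects
and a flat (ν = −2) scaled-inverse-χ² on σe². The σg² anchoring the class
variances is fixed at a preliminary GBLUP REML estimate on the same
training records, following the original formulation; a switch resamples it
each cycle. The optional polygenic term v ~ N(0, A σa²) is sampled through
the Cholesky factor of A and enters the residual structure but not the
GEBV, which is the (centered) genotype design times the posterior-mean SNP
effects. Production chain defaults: 50,000 cycles, 10,000 burn-in, keep
every 10th (4,000 retained samples); the test suite and acceptance script
run shortened chains (≈1,200–5,000 cycles), which our two-seed GEBV
correlation check (> 0.98) shows is adequate at these data sizes.

A structural caveat worth knowing: when the σg² anchor is at (or near) the
boundary — e.g. on a null trait — the three non-null classes become
likelihood-equivalent to the null class, and the posterior on the mixing
proportions reverts to its flat Dirichlet prior (π₀ ≈ 1/4) rather than
concentrating on the zero class. Effect sizes still shrink to zero; only
the class labels become uninformative.

## Weighted GBLUP

The iterative loop: D₀ = I; per iteration build G*(t) = 0.95·ZD(t)Z′/Σ2pq +
0.05·I, run GBLUP, back-solve marker effects û = (1/Σ2pq)·D·Z′·(G*)⁻¹·ĝ,
reweight d_jj = û_j²·2p_j(1−p_j), and renormalize so tr(D) = m. Four
iterations are run and stored; iteration 3 is reported. Variance
components are estimated once at iteration 0 and reused by default:
re-estimating on the reweighted kernel lets REML credit the
phenotype-tuned kernel ever more variance (we measured ĥ² inflating from
0.27 to 0.75 over four rounds) and degrades the predictions;
`refit_variances=True` restores per-iteration estimation. Even with frozen
variances the quadratic self-reweighting keeps concentrating: at n ≈ 1,000
the GEBV correlation between iterations 3 and 4 is about 0.995–0.998, and
on the default (moderately polygenic) architecture accuracy drifts slightly
below plain GBLUP, while on sparse architectures (a handful of large QTL)
the weighting is clearly beneficial. Zero-variance markers get weight 0;
an all-zero back-solution falls back to uniform weights with a warning.

## GWAS features and GFBLUP

The association scan is the standard two-stage mixed-linear-model
approximation: one null-model REML (σa², σe² with the all-marker G), then a
GLS Wald test per marker with the fitted covariance held fixed. The tested
marker stays in G (proximal contamination accepted; a switch exists).
Feature selection keeps markers with raw p < 0.05 — deliberately
uncorrected, as the point is enrichment, not discovery. Degenerate feature
sets (empty, or all markers) trigger a documented GBLUP fallback. Type-I
error and p-value uniformity are calibrated on an unrelated
linkage-equilibrium panel; on strongly family-structured null data the
two-stage approximation can be conservative or anticonservative depending
on where the boundary REML estimate lands — a known small-sample property
of the approximation, worth remembering when interpreting feature counts on
real family data.

## Cross-validation, reductions, cost

Fivefold CV with balanced uniformly-random folds; the same per-replicate
fold assignment drives every method and every reduction scenario, so all
contrasts are paired. Accuracy is r(y, GEBV)/√h² on raw phenotypes (an
adjusted-y variant exists behind a flag); dispersion bias is the OLS slope
of y on GEBV.

LD pruning considers all marker pairs within a 50-marker window on the same
chromosome, greedily drops the lower-MAF member of any pair with r² above a
threshold, and bisects the threshold so the retained count lands on the
target (exact count reached by trimming the most redundant survivors or
restoring the least redundant casualties, ranked by within-window max r²).
Reference reduction removes ⌊ratio·size⌋ members per full-sib family within
the training set only, skipping families too small to lose that many, so
the family count is preserved; "ratio" means the fraction removed.

Genotyping cost is strictly linear: head-count × per-sample price, with
prices $60 (HD), $50 (10K), $30 (5K), $30 (3K), $20 (1K), $10 (0.5K). The
3K price follows the published cost table and the headline "50% lower than
HD" arithmetic, both of which imply $30/sample for the 3K panel even though
the accompanying price list text reads $25; prices are overridable. The
four scenario costs per population: all-HD; all-3K; HD with the reference
share (fold fraction 0.8 of animals) cut by 10%, i.e. a genotyped fraction
of 0.92; and the same head-count at 3K. Head-counts stay fractional by
default because the published scenario-3 values imply non-integer counts.

## Problem sizes used by the tests

The suite runs on simulated populations of n ≈ 900–1,100 (84 families) with
1K–12K markers, 5 CV replicates for the directional checks, 20 seeds per h²
level for REML recovery, and shortened BayesR chains; the acceptance script
uses 3 replicates. These sizes were chosen to keep a full desk run in
minutes while leaving each check comfortably powered; all are set in one
place (`tests/conftest.py`, script constants) if larger runs are wanted.

## Known limitations

- Absolute accuracies from the real fish datasets are not reproducible from
  simulation; only directions and stability patterns are checked.
- The WGBLUP iteration-3 report is a convention, not a convergence point:
  successive-iteration GEBV correlations plateau near 0.995–0.998 at these
  scales.
- Single-trait, additive-only models; no ssGBLUP/H-matrix, no LD-aware
  imputation, no binary PLINK I/O.
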