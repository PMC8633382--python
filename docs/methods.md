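# Methods

## Model

For one SNP and *p* quantitative traits measured on *n* individuals, the
multi-trait single-marker regression stacks *p* equations with a common
design — the mean-centered genotype vector **x** — and within-subject error
correlation:

    y_j = x β_j + ε_j,   (ε_i1, …, ε_ip) ~ MVN(0, R) independently over i.

Phenotypes enter the model already centered and linearly adjusted for
covariates (age, sex, centers, genotype-derived PCs, …) by per-trait least
squares; heavy-tailed traits may be log-transformed first (per-trait `log`
flag, never auto-detected). With balanced data the GLS/ML ("seemingly
unrelated regressions") estimator reduces to per-trait OLS slopes,

    β̂_j = x'y_j / x'x,    cov(β̂) = R/(x'x),

because all equations share the same design.

## The error-covariance approximation S

R is unknown. Re-estimating it from per-SNP residuals doubles the work for
every variant, so the engine instead uses **S**, the covariance of the
adjusted phenotypes themselves, computed once per dataset. The difference
S − R̂ equals (x'x)·β̂β̂'/(n−1), a positive semi-definite rank-one term, so
tests based on S can only be conservative, and only materially so when the
SNP's effect is large — exactly the regime where power is near 1 regardless.
The Monte Carlo studies below quantify this: the stage-2 rejection rate
under a single strong effect stays within a hair of nominal at n = 3000.

Under missingness S is computed from **pairwise-complete** products
(S_jk = Σ y_ij y_ik / (n_jk − 1) over jointly observed samples); each pair
must be jointly observed in ≥ 3 samples. A pairwise-complete matrix need not
be positive definite, so eigenvalues are clipped at 1e-8 times the largest
eigenvalue when needed (logged; `repaired` flag). Pairwise completion keeps
the single-pass property; complete-case estimation would discard most of an
unbalanced dataset.

## Unbalanced data: pattern-grouped GLS

Samples are partitioned by their missing-value pattern (the subset of
observed traits). Given the block-diagonal error covariance with block
S_g = S[mask_g, mask_g] for pattern group g, the GLS normal equations
decompose into per-group sufficient statistics:

    A = Σ_g (x'x)_g · E_g' S_g⁻¹ E_g,    b = Σ_g E_g' S_g⁻¹ (x'Y)_g,
    β̂ = A⁻¹ b,    cov(β̂) = A⁻¹,

with E_g the selection matrix of the group's observed traits. The S_g⁻¹
pieces are precomputed once per scan; each SNP then costs one pass of
per-group cross products plus one p×p symmetric solve. This is the unique
GLS for that block structure and is verified against a brute-force
observation-level construction (explicit block-diagonal Ω, dense inverses)
on hundreds of random instances to ~1e-15 relative error. Missingness is
assumed non-informative; the estimator is then unbiased (a weighted average
of unbiased group-wise estimators), which the test suite checks by
simulation.

Two deliberate conventions:

* **Genotype centering is global** (over all analyzed samples), not within
  each pattern group — one consistent x per SNP.
* **Missing genotypes are mean-imputed** before centering (imputed entries
  become exactly 0, contributing nothing to x'x or x'Y) rather than spawning
  extra missingness patterns; after the 95% call-rate filter this touches at
  most 5% of entries per variant. Both choices could in principle differ
  from other implementations of the approach.

Groups smaller than `min_group_size` (default 1, i.e. keep everything;
n < 50 is a sensible opt-in for highly fragmented data) are dropped with a
logged sample count, trading a little data for bounded fragmentation.

## Sequential intersection-union testing

Stage s tests H_a: "the SNP affects at least s traits". All component nulls
are linear constraints Cβ = 0 with Wald statistic
w = β̂'C'[C cov(β̂) C']⁻¹Cβ̂ ~ χ²_rank(C). Stage 1 is the global test
(df = p). For stage s ≥ 2 the null is a union over all C(p, s−1) subsets of
p − s + 1 traits being all-zero; the IU p-value is the χ²_{p−s+1} upper tail
at the minimum component statistic (equivalently the maximum component
p-value — for p = 2, stage 2 is exactly the larger of the two marginal Wald
p-values, an identity the tests assert). Enumeration is capped at p ≤ 15
(2^p growth; at p = 15, stage 8 has 6435 component nulls).

Reported per-stage p-values are raw; the declared pleiotropy order at level
α is the largest s with *all* stages 1..s below α. No further within-locus
multiplicity adjustment is needed — the sequential gating provides it. An
early-stop threshold (e.g. 0.01) skips later stages once a stage's p-value
exceeds it; untested stages are reported as absent, never as 1.0. P-values
are floored at 1e-300, with −log10 values computed from the χ² log-survival
function so extreme signals remain distinguishable.

## Monte Carlo engine

One replicate draws an allele frequency f ~ Uniform(0.01, 0.5) (a pluggable
stand-in for an empirical MAF distribution), genotypes x_i ~ Binomial(2, f),
and traits y_ji = x_i β_j + ε_ji with homogeneous error correlation ρ and
per-trait error variance 1 − h²_j, so each trait has total variance 1 and
"fraction of variance explained" is exact: β₁ = √(h²/(2f(1−f))), other
affected traits carry `effect_ratio`·β₁. Every replicate runs the full
pipeline on itself: its own centered phenotypes give S, the balanced GLS
gives β̂ and cov(β̂), the stages give the decision.

Two execution modes produce the replicate statistics:

* **full** — simulate the n×p matrix explicitly and reduce it (reference
  path, also exercised replicate-by-replicate against the grouped engine).
* **sufficient** (default for studies) — sample the sufficient statistics
  directly from their exact sampling distributions: genotype counts
  (n₀,n₁,n₂) ~ Multinomial give x'x exactly; the cross product of errors
  with the centered-genotype direction is g ~ N(0, Σ); and the remaining
  centered error scatter is Wishart_p(n−2, Σ), drawn by Bartlett
  decomposition (n−2 because centering and the genotype direction each
  remove one dimension). The joint law of (x'x, x'Y, S) is identical to the
  full simulation — this is a collapse onto sufficient statistics, not an
  approximation — at roughly 1/300 the cost, which is what makes
  million-replicate calibration studies a few-second affair on one core.
  The test suite checks both the exact per-replicate agreement of the
  reduction and the statistical agreement of rejection rates between modes.

Study sizes used by the validation suite: 5×10⁵ replicates for the α = 0.01
calibration points, 10⁶ for α = 0.001 (Monte Carlo SE ≈ 0.006 and 0.014 on
the −log10 scale respectively), 10⁴ replicates per power cell, 10⁵ for the
conservativeness bound. Type-I designs: the global null (all β = 0, stage-1
test) and the single-effect design (trait 1 explains 1% of variance, stage-2
test — a composite null for two-trait pleiotropy). Rejection in these
studies is the target stage's own p-value below α; requiring the earlier
stages too (gating) can only lower the rate and is available via
`power_study(..., gate=True)`. The power study defaults to stage 2 at
α = 0.05; both are parameters, since the rejection rule behind any given
power figure is a reporting choice.

## Variant QC and post-processing

Variants are kept when minor-allele frequency ≥ 0.001 **and** call rate
≥ 0.95 (inclusive thresholds at the printed boundaries). Genome-wide
significance defaults to p < 1e-8, strict. Significant SNPs are merged per
chromosome into non-overlapping regions by transitive (single-linkage)
merging of SNPs closer than `gap_bp` (default 1 Mbp); region bounds are the
member min/max positions (1-based, closed), the lead SNP is the smallest
p-value (ties → smaller bp), a region's order is the maximum member order
and its trait mask the union of member masks. Per-SNP **trait attribution**
flags traits with marginal single-trait p below a threshold, falling back to
the `order` smallest marginal p-values (marked "forced") when fewer pass —
a reporting convention of this package, labelled as such, since the
attribution rule behind published region-by-trait tables is not uniquely
determined by the test itself. Pairwise tables count regions (and member
SNPs) whose mask contains both traits of a pair.

Dosages count copies of the A1 allele (fifth `.bim` column). Allele flips
negate β̂ and leave every p-value unchanged (tested). Only SNP-major `.bed`
is supported; positions are 1-based throughout.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the test operates on:
binomial genotypes in Hardy–Weinberg proportions, Gaussian errors with
homogeneous correlation, exact variance bookkeeping, pattern-structured
missingness, covariate effects for the adjustment path. It does **not**
emulate linkage disequilibrium between variants (each simulated variant is
independent, so region grouping is exercised on positions, not on realistic
LD blocks), population structure or relatedness, non-Gaussian trait
distributions, or informative missingness. Passing tests therefore validate
the estimator, the test's calibration, and the plumbing — not robustness to
confounding, which in real analyses is handled upstream (PC adjustment,
relatedness filtering) as in any standard GWAS pipeline.

## Numerical choices and limitations

* Symmetric positive-definite solves (Cholesky) everywhere; explicit
  inverses only for the returned p×p covariance.
* A singular per-SNP system (e.g. a trait with no genotype variance in its
  groups) yields a per-SNP skip record, never an aborted scan; every input
  variant appears exactly once in the results or the skip log.
* Monomorphic and all-missing variants are skipped with logged reasons.
* Chunked scans are byte-identical to single-pass scans (per-SNP
  independence; tested), so chromosome- or chunk-level parallelism is safe.
* The sequential test assumes multivariate-normal errors; for strongly
  non-normal traits, transform first. Generalized-linear-model outcomes and
  summary-statistic input are out of scope.
* Known limitation: apparent pleiotropy can arise from LD between distinct
  causal variants affecting different traits; the test cannot distinguish
  this from true pleiotropy.
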