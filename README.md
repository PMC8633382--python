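# pleioscan

Fast sequential Wald tests for mapping **pleiotropic loci** — variants with
simultaneous effects on two or more traits — in multi-trait GWAS at biobank
scale.

## Who this is for

Statistical geneticists running whole-genome scans over systems of
quantitative traits (e.g., metabolic-syndrome panels) who want a formal,
error-controlled answer to "does this SNP affect at least *s* of my *p*
traits?" rather than ad-hoc overlap of single-trait hits. The package reads
PLINK binary genotypes (`.bed/.bim/.fam`) through a memory map, handles
unbalanced phenotype data (samples missing some traits), and includes a
Monte Carlo engine for validating calibration and power.

## The model and the test

For each SNP, the *p* traits are regressed jointly on the mean-centered
genotype **x** (seemingly unrelated regressions with a shared design):

```
y_j = x β_j + ε_j ,   j = 1..p,   ε row-covariance R
```

The GLS/ML estimator of the effect vector and its sampling covariance in the
balanced case are

```
β̂_j = x'y_j / x'x ,      cov(β̂) = R / (x'x).
```

Because one SNP explains only a small fraction of a complex trait's variance,
**R** is replaced by **S**, the covariance of covariate-adjusted, centered
phenotypes, computed *once* per dataset. `S − R̂` is positive semi-definite,
so inference is at most slightly conservative — and only when power is very
high anyway.

Pleiotropy is then tested by a **sequence of Wald intersection-union tests**.
Stage 1 ("effect on ≥ 1 trait") uses `w₀ = β̂' cov(β̂)⁻¹ β̂ ~ χ²_p`. Stage
*s* ≥ 2 ("effects on ≥ s traits") has a union null — some set of
`p − s + 1` traits has all-zero effects; the IU p-value is the χ²
(df = `p − s + 1`) upper tail at the **minimum** Wald statistic over all such
zero sets. A SNP is declared pleiotropic of order *s* at level α only when
all stages 1..s reject, which controls the error rate across the sequence.

With missing phenotype data, samples are grouped by missing-value pattern;
each group contributes cheap sufficient statistics (`x'x`, `x'Y` restricted
to its observed traits) that combine into the exact GLS normal equations for
the block-diagonal error covariance.

## Worked example

```bash
echo '{"n": 2000, "p": 3, "rho": 0.3, "h2": 0.05, "ratio": 1.0,
       "affected": [0, 1], "n_variants": 30, "seed": 5}' > sim.json
pleioscan simulate --config sim.json --out demo
pleioscan run --bed demo.bed --bim demo.bim --fam demo.fam \
              --pheno demo.pheno.tsv --out scan
pleioscan regions --results scan.results.tsv --out reg
```

This simulates 2000 samples, three traits with error correlation 0.3, and 30
variants, one of which (snp1) explains 5% of the variance of traits 1 and 2.
The scan prints `tested 30 variants, skipped 0`; the causal row of
`scan.results.tsv` reads (abridged):

```
id    bp       beta_trait1  beta_trait2  beta_trait3  p_stage1   p_stage2   p_stage3
snp1  1000000  0.322        0.317        0.027        3.8e-35    4.5e-22    0.41
```

Stages 1 and 2 are far below the genome-wide threshold 1e-8 while stage 3 is
not: the SNP affects *at least two* traits, and the effect estimates (true
value ≈ 0.32 at the simulated allele frequency) are recovered within one
standard error. `reg.regions.tsv` then reports one region of order 2
attributed to `trait1,trait2`, and `reg.pairwise.tsv` counts that region for
the (trait1, trait2) pair — the same region/pair bookkeeping used for
reporting shared loci across a trait system.

The same machinery is available as a library
(`pleioscan.run_scan`, `pleioscan.sequential_pvalues`,
`pleioscan.type1_study`, ...); see `docs/methods.md` for the statistical
details and design choices.

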