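"""Monte Carlo engine and synthetic-data generator.

One replicate draws a biallelic variant x_i ~ Binomial(2, f) with f from a
minor-allele-frequency law (default Uniform(0.01, 0.5)) and p traits

    y_ji = x_i * beta_j + eps_ji,

with multivariate-normal errors whose correlation is homogeneous (rho) and
whose per-trait variance is 1 - h2_j, so the total phenotypic variance is 1
per trait and "fraction of variance explained" is exact. The effect on trait
one is beta_1 = sqrt(h2 / (2 f (1 - f))); other affected traits carry
effect_ratio * beta_1.

Every replicate runs the full pipeline on itself: the replicate's centered
phenotypes give S, the balanced GLS fit gives the effects (per-trait OLS
slopes with covariance S/(x'x), identical to the grouped path with one
complete group), and the sequential Wald stages give the decision.

Two execution modes produce the replicate statistics:

* ``method="full"`` simulates the n x p data matrix explicitly and reduces it.
* ``method="sufficient"`` (default for studies) samples the replicate's
  sufficient statistics directly from their exact sampling distributions --
  genotype counts from a multinomial, the genotype-error cross product from
  N(0, Sigma), and the centered error scatter from a Wishart with n - 2
  degrees of freedom via the Bartlett decomposition (the projection removing
  the column means and the genotype direction). The joint distribution of
  (x'x, x'Y, S) is identical to the full simulation, so rejection rates are
  estimates of the same quantities at a small fraction of the cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import plink_io
from .plink_io import SampleRecord, VariantRecord


@dataclass
class SimulationSetting:
    """Study conditions for one Monte Carlo cell or one synthetic fixture."""

    n: int = 3000
    p: int = 3
    rho: float = 0.2
    maf_law: tuple[float, float] = (0.01, 0.5)  # Uniform(lo, hi)
    h2_trait1: float = 0.0
    effect_ratio: float = 1.0
    affected_traits: tuple[int, ...] = ()
    #: list of (observed trait indices, fraction of samples); the remaining
    #: fraction is fully observed
    missing_pattern_spec: list[tuple[tuple[int, ...], float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_trait1 < 1.0:
            raise ValueError("h2_trait1 must be in [0, 1)")
        if self.p >= 2 and not (-1.0 / (self.p - 1) < self.rho < 1.0):
            raise ValueError(f"rho must be in (-1/(p-1), 1) for p={self.p}")
        lo, hi = self.maf_law
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_law support must lie in (0, 0.5]")
        if any(not 0 <= j < self.p for j in self.affected_traits):
            raise ValueError("affected_traits indices out of range")

    def h2_per_trait(self) -> np.ndarray:
        """Variance fraction explained by the variant on each trait."""
        h2 = np.zeros(self.p)
        for j in self.affected_traits:
            h2[j] = self.h2_trait1 * (1.0 if j == 0 else self.effect_ratio**2)
        return h2

    def error_cov(self) -> np.ndarray:
        """Error covariance: diag 1 - h2_j, homogeneous correlation rho."""
        sd = np.sqrt(1.0 - self.h2_per_trait())
        Sigma = self.rho * np.outer(sd, sd)
        np.fill_diagonal(Sigma, sd**2)
        return Sigma

    def _effect_base(self) -> np.ndarray:
        base = np.zeros(self.p)
        for j in self.affected_traits:
            base[j] = 1.0 if j == 0 else self.effect_ratio
        return base

    def effect_vector(self, f: np.ndarray | float) -> np.ndarray:
        """Per-trait effects given allele frequency f (beta_1 scaled so the
        variant explains h2_trait1 of trait one's variance)."""
        f = np.asarray(f, dtype=np.float64)
        var_x = 2.0 * f * (1.0 - f)
        beta1 = np.sqrt(self.h2_trait1 / var_x)
        base = self._effect_base()
        return np.multiply.outer(beta1, base) if f.ndim else beta1 * base


@dataclass
class RateEstimate:
    """Empirical rejection rate with a normal-approximation 95% interval."""

    alpha: float
    rate: float
    ci: tuple[float, float]
    n_reps: int

    @property
    def neglog10_rate(self) -> float:
        return -math.log10(self.rate) if self.rate > 0 else math.inf

    @property
    def neglog10_ci(self) -> tuple[float, float]:
        lo, hi = self.ci
        f = lambda r: -math.log10(r) if r > 0 else math.inf
        return (f(hi), f(lo))


def _make_rate(k: int, n_reps: int, alpha: float) -> RateEstimate:
    rate = k / n_reps
    se = math.sqrt(max(rate * (1.0 - rate), 0.0) / n_reps)
    ci = (max(rate - 1.96 * se, 0.0), min(rate + 1.96 * se, 1.0))
    return RateEstimate(alpha=alpha, rate=rate, ci=ci, n_reps=n_reps)


def _draw_genotypes(rng: np.random.Generator, f: np.ndarray, n: int) -> np.ndarray:
    """x ~ Binomial(2, f) drawn as the sum of two Bernoulli indicators, which
    vectorizes cheaply across replicates with replicate-specific f."""
    B = f.shape[0]
    x = (rng.random((B, n)) < f[:, None]).astype(np.float64)
    x += rng.random((B, n)) < f[:, None]
    return x


def _apply_missing_patterns(
    Y: np.ndarray,
    spec: list[tuple[tuple[int, ...], float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """NaN-out traits according to (observed set, fraction) pattern specs;
    samples are assigned to patterns at random without replacement."""
    n, p = Y.shape
    fractions = [frac for _, frac in spec]
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError("missing-pattern fractions sum to more than 1")
    perm = rng.permutation(n)
    start = 0
    for observed, frac in spec:
        cnt = int(round(frac * n))
        rows = perm[start : start + cnt]
        start += cnt
        hidden = np.setdiff1d(np.arange(p), np.asarray(observed, dtype=int))
        Y[np.ix_(rows, hidden)] = np.nan
    return Y


def simulate_dataset(
    setting: SimulationSetting, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate: genotype dosages (n,) and traits (n, p)."""
    if rng is None:
        rng = np.random.default_rng(setting.seed)
    f = rng.uniform(*setting.maf_law, size=1)
    x = _draw_genotypes(rng, f, setting.n)[0]
    L = np.linalg.cholesky(setting.error_cov())
    eps = rng.standard_normal((setting.n, setting.p)) @ L.T
    beta = setting.effect_vector(float(f[0]))
    Y = eps + x[:, None] * beta[None, :]
    if setting.missing_pattern_spec:
        Y = _apply_missing_patterns(Y, setting.missing_pattern_spec, rng)
    return x, Y


# ---------------------------------------------------------------------------
# batched replicate statistics


def stage_stats_from_moments(
    xtx: np.ndarray, xty: np.ndarray, S: np.ndarray, stages: tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Minimum Wald statistic per stage for a batch of balanced replicates,
    given each replicate's sufficient statistics: xtx (B,), xty (B, p) and the
    centered-phenotype covariance S (B, p, p).

    Per replicate: beta_j = xty_j / xtx with covariance S/xtx, then the
    stage's component quadratic forms are minimised. Replicates with xtx = 0
    (monomorphic genotype draw) return NaN.
    """
    B, p = xty.shape
    ok = xtx > 0
    safe = np.where(ok, xtx, 1.0)
    beta = xty / safe[:, None]
    cov = S / safe[:, None, None]
    out: dict[int, np.ndarray] = {}
    for stage in stages:
        if not 1 <= stage <= p:
            raise ValueError(f"stage {stage} out of range for p={p}")
        size = p - stage + 1
        w_min = np.full(B, np.inf)
        for zs in combinations(range(p), size):
            K = np.asarray(zs, dtype=np.intp)
            bK = beta[:, K]
            covK = cov[:, K[:, None], K[None, :]]
            w = _batched_quadform(bK, covK)
            np.minimum(w_min, w, out=w_min)
        w_min[~ok] = np.nan
        out[stage] = w_min
    return out


def _batched_quadform(b: np.ndarray, C: np.ndarray) -> np.ndarray:
    """b' inv(C) b per batch element, with closed forms for k <= 2."""
    k = b.shape[1]
    if k == 1:
        return b[:, 0] ** 2 / C[:, 0, 0]
    if k == 2:
        det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
        num = (
            b[:, 0] ** 2 * C[:, 1, 1]
            - 2.0 * b[:, 0] * b[:, 1] * C[:, 0, 1]
            + b[:, 1] ** 2 * C[:, 0, 0]
        )
        return num / det
    sol = np.linalg.solve(C, b[..., None])[..., 0]
    return np.einsum("bk,bk->b", b, sol)


def batched_stage_stats(
    x: np.ndarray, Y: np.ndarray, stages: tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Stage statistics from explicit replicate data (x: reps x n,
    Y: reps x n x p): center, reduce to sufficient statistics, test."""
    x = np.asarray(x, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    B, n = x.shape
    xbar = x.mean(axis=1)
    ybar = Y.mean(axis=1)
    xtx = np.einsum("bn,bn->b", x, x) - n * xbar**2
    xty = np.einsum("bn,bnp->bp", x, Y) - n * xbar[:, None] * ybar
    yty = np.matmul(Y.transpose(0, 2, 1), Y) - n * ybar[:, :, None] * ybar[:, None, :]
    S = yty / (n - 1)
    return stage_stats_from_moments(xtx, xty, S, stages)


def _sample_sufficient_stats(
    rng: np.random.Generator, setting: SimulationSetting, B: int, L: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (xtx, xty, S) for B replicates from their exact distributions.

    Genotype counts (n0, n1, n2) ~ Multinomial(n, ((1-f)^2, 2f(1-f), f^2))
    give xtx = n1 + 4 n2 - n xbar^2 exactly. Writing u for the unit vector
    along the centered genotype, g = E'u ~ N(0, Sigma) and the remaining
    centered error scatter W ~ Wishart_p(n - 2, Sigma) are independent, so

        x'Y   = xtx * beta + sqrt(xtx) * g
        (n-1) S = xtx beta beta' + sqrt(xtx)(beta g' + g beta') + g g' + W.
    """
    n, p = setting.n, setting.p
    f = rng.uniform(*setting.maf_law, size=B)
    pvals = np.column_stack([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])
    counts = rng.multinomial(n, pvals)
    n1 = counts[:, 1].astype(np.float64)
    n2 = counts[:, 2].astype(np.float64)
    xbar = (n1 + 2.0 * n2) / n
    xtx = n1 + 4.0 * n2 - n * xbar**2

    g = rng.standard_normal((B, p)) @ L.T

    # Bartlett: W = (L T)(L T)', T lower-triangular, T_ii^2 ~ chi2(n-2-i)
    T = np.zeros((B, p, p))
    for i in range(p):
        T[:, i, i] = np.sqrt(rng.chisquare(n - 2 - i, size=B))
        if i:
            T[:, i, :i] = rng.standard_normal((B, i))
    LT = L @ T  # broadcasts over the batch
    W = np.matmul(LT, LT.transpose(0, 2, 1))

    sqrt_xtx = np.sqrt(xtx)
    base = setting._effect_base()
    if setting.h2_trait1 > 0.0 and base.any():
        beta1 = np.sqrt(setting.h2_trait1 / (2.0 * f * (1.0 - f)))
        beta = beta1[:, None] * base[None, :]
    else:
        beta = np.zeros((B, p))
    xty = xtx[:, None] * beta + sqrt_xtx[:, None] * g
    bg = beta[:, :, None] * g[:, None, :]
    Sn = (
        xtx[:, None, None] * beta[:, :, None] * beta[:, None, :]
        + sqrt_xtx[:, None, None] * (bg + bg.transpose(0, 2, 1))
        + g[:, :, None] * g[:, None, :]
        + W
    )
    return xtx, xty, Sn / (n - 1)


def _default_batch(n: int, p: int, n_reps: int, method: str) -> int:
    if method == "sufficient":
        return min(n_reps, 200_000)
    return max(64, min(n_reps, (1 << 25) // max(n * p, 1)))


def _run_batches(
    setting: SimulationSetting,
    n_reps: int,
    stages: tuple[int, ...],
    rng: np.random.Generator,
    batch_size: int | None,
    method: str,
):
    """Yield dicts of stage -> minimum-Wald arrays until n_reps are done."""
    if method not in ("sufficient", "full"):
        raise ValueError(f"unknown simulation method {method!r}")
    if batch_size is None:
        batch_size = _default_batch(setting.n, setting.p, n_reps, method)
    L = np.linalg.cholesky(setting.error_cov())
    base = setting._effect_base()
    done = 0
    while done < n_reps:
        B = min(batch_size, n_reps - done)
        if method == "sufficient":
            xtx, xty, S = _sample_sufficient_stats(rng, setting, B, L)
            yield stage_stats_from_moments(xtx, xty, S, stages)
        else:
            f = rng.uniform(*setting.maf_law, size=B)
            x = _draw_genotypes(rng, f, setting.n)
            Y = rng.standard_normal((B, setting.n, setting.p)) @ L.T
            if setting.h2_trait1 > 0.0 and base.any():
                beta1 = np.sqrt(setting.h2_trait1 / (2.0 * f * (1.0 - f)))
                Y += x[:, :, None] * (beta1[:, None] * base[None, :])[:, None, :]
            yield batched_stage_stats(x, Y, stages)
        done += B


def type1_study(
    setting: SimulationSetting,
    n_reps: int,
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
    target_stage: int = 1,
    seed: int | None = None,
    batch_size: int | None = None,
    method: str = "sufficient",
) -> list[RateEstimate]:
    """Empirical rejection rate of the target-stage test over null replicates.

    With no effects anywhere the stage-1 test is the null being violated
    ("effect on at least one trait"); with an effect on trait one only, the
    stage-2 test ("effects on at least two traits") is the null case. The
    rejection rule is the target stage's p-value below alpha (earlier-stage
    gating could only lower the rate and is studied separately).
    """
    min_alpha = min(alphas)
    if n_reps < 10.0 / min_alpha:
        warnings.warn(
            f"{n_reps} replicates give <10 expected rejections at alpha={min_alpha}",
            stacklevel=2,
        )
    rng = np.random.default_rng(setting.seed if seed is None else seed)
    df = setting.p - target_stage + 1
    crit = sps.chi2.isf(np.asarray(alphas), df)
    counts = np.zeros(len(alphas), dtype=np.int64)
    n_valid = 0
    for stats in _run_batches(setting, n_reps, (target_stage,), rng, batch_size, method):
        w = stats[target_stage]
        w = w[np.isfinite(w)]
        n_valid += w.size
        counts += (w[:, None] > crit[None, :]).sum(axis=0)
    return [_make_rate(int(k), n_valid, a) for k, a in zip(counts, alphas)]


def power_study(
    settings: list[SimulationSetting],
    n_reps: int,
    alpha: float = 0.05,
    target_stage: int = 2,
    gate: bool = False,
    seed: int | None = None,
    batch_size: int | None = None,
    method: str = "sufficient",
) -> pd.DataFrame:
    """Rejection fraction of the target-stage sequential test per setting.

    With ``gate=True`` a replicate counts as a rejection only if every stage
    1..target_stage rejects at alpha (the declared-order rule); the default
    counts the target stage's own p-value, matching the type-I studies.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(settings))
    for setting, child in zip(settings, child_seeds):
        rng = np.random.default_rng(int(child))
        stages = tuple(range(1, target_stage + 1)) if gate else (target_stage,)
        crit = {s: sps.chi2.isf(alpha, setting.p - s + 1) for s in stages}
        k = 0
        n_valid = 0
        for stats in _run_batches(setting, n_reps, stages, rng, batch_size, method):
            valid = np.isfinite(stats[target_stage])
            rej = valid.copy()
            for s in stages:
                rej &= stats[s] > crit[s]
            k += int(rej.sum())
            n_valid += int(valid.sum())
        est = _make_rate(k, n_valid, alpha)
        rows.append(
            {
                "n": setting.n,
                "p": setting.p,
                "rho": setting.rho,
                "h2": setting.h2_trait1,
                "effect_ratio": setting.effect_ratio,
                "alpha": alpha,
                "stage": target_stage,
                "power": est.rate,
                "mc_se": math.sqrt(max(est.rate * (1 - est.rate), 0.0) / n_valid),
                "n_reps": n_valid,
            }
        )
    return pd.DataFrame(rows)


def write_fixture(
    setting: SimulationSetting,
    out_prefix: str | Path,
    n_variants: int = 50,
    causal_index: int = 0,
    n_covariates: int = 0,
    geno_missing_rate: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Write a synthetic PLINK fileset plus phenotype/covariate tables.

    One variant (``causal_index``) carries the setting's effects; the rest are
    independent null draws from the same allele-frequency law. Returns the
    file paths together with the simulation truth (causal frequency and
    per-trait effects) for parameter-recovery checks.
    """
    out_prefix = Path(out_prefix)
    rng = np.random.default_rng(setting.seed if seed is None else seed)
    n, p = setting.n, setting.p

    f_all = rng.uniform(*setting.maf_law, size=n_variants)
    X = _draw_genotypes(rng, f_all, n)  # variants x samples
    x_causal = X[causal_index]
    beta = setting.effect_vector(float(f_all[causal_index]))

    L = np.linalg.cholesky(setting.error_cov())
    Y = rng.standard_normal((n, p)) @ L.T + x_causal[:, None] * beta[None, :]

    gamma = None
    covar_path = None
    if n_covariates > 0:
        C = rng.standard_normal((n, n_covariates))
        gamma = np.full((n_covariates, p), 0.3)
        Y = Y + C @ gamma
    if setting.missing_pattern_spec:
        Y = _apply_missing_patterns(Y, setting.missing_pattern_spec, rng)
    if geno_missing_rate > 0.0:
        X[rng.random(X.shape) < geno_missing_rate] = np.nan

    variants = [
        VariantRecord(chrom="1", id=f"snp{i + 1}", bp=1_000_000 + 10_000 * i, a1="A", a2="G")
        for i in range(n_variants)
    ]
    samples = [SampleRecord(fid=f"F{i + 1}", iid=f"I{i + 1}") for i in range(n)]
    plink_io.write_bed(out_prefix.with_suffix(".bed"), X)
    plink_io.write_bim(out_prefix.with_suffix(".bim"), variants)
    plink_io.write_fam(out_prefix.with_suffix(".fam"), samples)

    pheno = pd.DataFrame(Y, columns=[f"trait{j + 1}" for j in range(p)])
    pheno.insert(0, "IID", [s.iid for s in samples])
    pheno.insert(0, "FID", [s.fid for s in samples])
    pheno_path = out_prefix.parent / (out_prefix.name + ".pheno.tsv")
    pheno.to_csv(pheno_path, sep="\t", index=False, na_rep="NA")

    if n_covariates > 0:
        covar = pd.DataFrame(C, columns=[f"cov{j + 1}" for j in range(n_covariates)])
        covar.insert(0, "IID", [s.iid for s in samples])
        covar.insert(0, "FID", [s.fid for s in samples])
        covar_path = out_prefix.parent / (out_prefix.name + ".covar.tsv")
        covar.to_csv(covar_path, sep="\t", index=False, na_rep="NA")

    return {
        "bed": out_prefix.with_suffix(".bed"),
        "bim": out_prefix.with_suffix(".bim"),
        "fam": out_prefix.with_suffix(".fam"),
        "pheno": pheno_path,
        "covar": covar_path,
        "truth": {
            "causal_id": variants[causal_index].id,
            "causal_index": causal_index,
            "f": float(f_all[causal_index]),
            "beta": beta,
            "gamma": gamma,
        },
    }
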