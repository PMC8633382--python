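"""Sequential Wald intersection-union tests for pleiotropy.

Stage s tests "the SNP affects at least s traits". Stage 1 is the global Wald
test beta' inv(cov) beta ~ chi-square with p degrees of freedom. For s >= 2
the null "fewer than s traits are affected" is a union of component nulls,
one per subset of p - s + 1 traits constrained to zero; the intersection-union
p-value is the chi-square (df = p - s + 1) upper tail at the minimum of the
component Wald statistics, equivalently the maximum component p-value. A SNP
is declared pleiotropic of order s at level alpha only when every stage
1..s rejects, which is what controls the error rate across the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.linalg
from scipy import stats as sps

from .gls_engine import EffectEstimate, SnpSkipped

#: numerical floor for reported p-values; -log10 values are computed from the
#: chi-square log-survival function and are not floored
P_FLOOR = 1e-300

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ContrastSet:
    """All component nulls of one stage: each zero_set is the subset of traits
    constrained to zero under one component null (size p - stage + 1)."""

    stage: int
    zero_sets: tuple[tuple[int, ...], ...]


@dataclass
class SnpResult:
    """Per-SNP scan output: effect estimate, stagewise IU statistics/p-values
    (untested stages are None, not 1.0) and single-trait marginal p-values."""

    variant: object
    effect: EffectEstimate | None
    stage_stats: list[float | None] = field(default_factory=list)
    stage_p: list[float | None] = field(default_factory=list)
    stage_neglog10: list[float | None] = field(default_factory=list)
    stages_tested: int = 0
    marginal_p: np.ndarray | None = None
    skip_reason: str | None = None


def build_contrasts(p: int, stage: int) -> ContrastSet:
    """Enumerate the stage's zero sets: all subsets of {0..p-1} of size
    p - stage + 1 (stage 2 with identity-matrix rows removed one at a time is
    the classical special case)."""
    if not 1 <= stage <= p:
        raise ValueError(f"stage must be in [1, {p}], got {stage}")
    if p > 15:
        raise ValueError("contrast enumeration capped at p <= 15 traits")
    size = p - stage + 1
    return ContrastSet(stage=stage, zero_sets=tuple(combinations(range(p), size)))


def wald_statistic(
    beta_hat: np.ndarray, cov_beta: np.ndarray, zero_set: tuple[int, ...]
) -> float:
    """Quadratic form beta_K' inv(cov_KK) beta_K for the traits K constrained
    to zero; the full set gives the global statistic."""
    K = np.asarray(zero_set, dtype=np.intp)
    bK = beta_hat[K]
    covK = cov_beta[np.ix_(K, K)]
    try:
        c = scipy.linalg.cho_factor(covK)
    except scipy.linalg.LinAlgError as exc:
        raise SnpSkipped(
            f"restricted covariance singular for zero set {tuple(zero_set)}"
        ) from exc
    w = float(bK @ scipy.linalg.cho_solve(c, bK))
    return max(w, 0.0)


def _chi2_tail(w: float, df: int) -> tuple[float, float]:
    """(p, -log10 p) from the chi-square upper tail, p floored at P_FLOOR."""
    logp = sps.chi2.logsf(w, df)
    p = max(float(np.exp(logp)), P_FLOOR)
    return p, float(-logp / _LN10)


def stage_pvalue(
    beta_hat: np.ndarray, cov_beta: np.ndarray, stage: int
) -> tuple[float, float, tuple[int, ...]]:
    """Minimum Wald statistic over the stage's component nulls and its
    chi-square (df = p - stage + 1) upper-tail p-value.

    Returns (w_min, p, driving zero set); ties resolve to the
    lexicographically smallest subset.
    """
    p_traits = beta_hat.shape[0]
    contrasts = build_contrasts(p_traits, stage)
    w_min, argmin = math.inf, contrasts.zero_sets[0]
    for zs in contrasts.zero_sets:
        w = wald_statistic(beta_hat, cov_beta, zs)
        if w < w_min:
            w_min, argmin = w, zs
    df = p_traits - stage + 1
    pval, _ = _chi2_tail(w_min, df)
    return w_min, pval, argmin


def marginal_pvalues(beta_hat: np.ndarray, cov_beta: np.ndarray) -> np.ndarray:
    """Single-trait Wald p-values: chi-square(1) upper tail at
    beta_j^2 / var(beta_j)."""
    z2 = beta_hat**2 / np.diag(cov_beta)
    return np.maximum(sps.chi2.sf(z2, 1), P_FLOOR)


def sequential_pvalues(
    beta_hat: np.ndarray,
    cov_beta: np.ndarray,
    max_stage: int | None = None,
    early_stop_p: float = 1.0,
) -> SnpResult:
    """Run stages 1, 2, ... in order, stopping after the first stage whose
    p-value exceeds ``early_stop_p`` (that stage's p is still recorded).

    Untested stages are reported as None. Use :func:`declared_order` to turn
    the recorded p-values into a pleiotropy order at a significance level.
    """
    p_traits = beta_hat.shape[0]
    if max_stage is None:
        max_stage = p_traits
    if not 1 <= max_stage <= p_traits:
        raise ValueError(f"max_stage must be in [1, {p_traits}]")
    res = SnpResult(variant=None, effect=None)
    res.stage_stats = [None] * max_stage
    res.stage_p = [None] * max_stage
    res.stage_neglog10 = [None] * max_stage
    for stage in range(1, max_stage + 1):
        w_min, _, _ = stage_pvalue(beta_hat, cov_beta, stage)
        pval, neglog10 = _chi2_tail(w_min, p_traits - stage + 1)
        res.stage_stats[stage - 1] = w_min
        res.stage_p[stage - 1] = pval
        res.stage_neglog10[stage - 1] = neglog10
        res.stages_tested = stage
        if pval > early_stop_p:
            break
    res.marginal_p = marginal_pvalues(beta_hat, cov_beta)
    return res


def declared_order(stage_p: list[float | None], alpha: float) -> int:
    """Largest s such that stages 1..s all have p < alpha (0 if stage 1 does
    not reject). Sequential gating: a gap at any earlier stage ends the run."""
    order = 0
    for pval in stage_p:
        if pval is not None and pval < alpha:
            order += 1
        else:
            break
    return order
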