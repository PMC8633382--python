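"""Per-SNP multi-trait GLS/SUR effect estimation.

The multi-trait single-marker model stacks p trait regressions on one
mean-centered genotype vector x with errors that are correlated within
subject (covariance R, approximated by S) and independent across subjects.
With balanced data the GLS estimator reduces to per-trait OLS slopes with
sampling covariance S / (x'x). With unbalanced data the error covariance is
block diagonal over missing-value pattern groups, so the normal equations
decompose into cheap per-group sufficient statistics (x'x and x'Y restricted
to the group) that are combined once per SNP:

    A = sum_g xtx_g * Eg' inv(S_g) Eg        (p x p)
    b = sum_g Eg' inv(S_g) xty_g             (p,)
    beta_hat = inv(A) b,   cov(beta_hat) = inv(A)

where S_g is S restricted to the group's observed traits and Eg the
corresponding selection matrix. This is the unique GLS given that block
structure; missingness is assumed non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocess import AdjustedPhenotypeMatrix, PatternGroup


class SnpSkipped(Exception):
    """A single variant cannot be tested; the scan records the reason and
    continues."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class GroupSufficientStats:
    """Sufficient statistics of one pattern group for one SNP: xtx = sum of
    squared centered genotypes over members, xty = genotype-phenotype cross
    products for the group's observed traits."""

    xtx: float
    xty: np.ndarray
    group: PatternGroup


@dataclass
class EffectEstimate:
    beta_hat: np.ndarray  # p-vector, trait units per A1-allele copy
    cov_beta: np.ndarray  # p x p sampling covariance
    n_used: int


@dataclass
class GroupWeights:
    """Per-group pieces of the normal equations that do not depend on the SNP;
    precomputed once per scan."""

    scatter: list[np.ndarray]  # Eg' inv(S_g) Eg, each p x p
    solve_in: list[np.ndarray]  # inv(S_g), each k_g x k_g
    trait_idx: list[np.ndarray]
    n_traits: int


def center_genotype(
    dosage: np.ndarray, analyzed_samples: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Mean-impute missing dosages and mean-center over the analyzed samples.

    Imputed entries are exactly 0 after centering, so they contribute nothing
    to x'x or x'y. Returns the centered vector (zero outside the analyzed set)
    and the number of imputed entries. Raises :class:`SnpSkipped` for variants
    that are all-missing or monomorphic within the analyzed samples.
    """
    dosage = np.asarray(dosage, dtype=np.float64)
    x = np.zeros_like(dosage)
    if analyzed_samples is None:
        analyzed_samples = np.arange(dosage.shape[0])
    d = dosage[analyzed_samples]
    obs = np.isfinite(d)
    n_missing = int((~obs).sum())
    if not obs.any():
        raise SnpSkipped("all genotypes missing in analyzed samples")
    mean = d[obs].mean()
    d = np.where(obs, d, mean) - mean
    if not np.any(d != 0.0):
        raise SnpSkipped("monomorphic in analyzed samples (x'x = 0)")
    x[analyzed_samples] = d
    return x, n_missing


def accumulate_group_stats(
    x_centered: np.ndarray,
    adjusted: AdjustedPhenotypeMatrix,
    groups: list[PatternGroup],
) -> list[GroupSufficientStats]:
    """Per group g: xtx_g = sum_i x_i^2, xty_gj = sum_i x_i y_ij over the
    group's members, for the traits observed in the group."""
    stats = []
    for g in groups:
        xg = x_centered[g.member_indices]
        cols = np.flatnonzero(g.trait_mask)
        yg = adjusted.values[np.ix_(g.member_indices, cols)]
        stats.append(
            GroupSufficientStats(xtx=float(xg @ xg), xty=xg @ yg, group=g)
        )
    return stats


def precompute_group_weights(S: np.ndarray, groups: list[PatternGroup]) -> GroupWeights:
    """Invert S restricted to each group's trait mask, once per scan."""
    p = S.shape[0]
    scatter, solve_in, trait_idx = [], [], []
    for g in groups:
        cols = np.flatnonzero(g.trait_mask)
        Sg = S[np.ix_(cols, cols)]
        try:
            Sg_inv = scipy.linalg.cho_solve(scipy.linalg.cho_factor(Sg), np.eye(len(cols)))
        except scipy.linalg.LinAlgError as exc:
            raise ValueError(
                f"error covariance restricted to traits {cols.tolist()} is not "
                "positive definite"
            ) from exc
        M = np.zeros((p, p))
        M[np.ix_(cols, cols)] = Sg_inv
        scatter.append(M)
        solve_in.append(Sg_inv)
        trait_idx.append(cols)
    return GroupWeights(scatter=scatter, solve_in=solve_in, trait_idx=trait_idx, n_traits=p)


def gls_fit(
    stats: list[GroupSufficientStats],
    S: np.ndarray | None = None,
    weights: GroupWeights | None = None,
) -> EffectEstimate:
    """Combine per-group sufficient statistics into the GLS estimate.

    Either the error covariance ``S`` or precomputed :class:`GroupWeights`
    must be given. The balanced single-group case reduces exactly to
    beta_j = x'y_j / x'x with covariance S / (x'x).
    """
    if not stats:
        raise SnpSkipped("no pattern groups with data")
    if weights is None:
        if S is None:
            raise ValueError("provide S or precomputed weights")
        weights = precompute_group_weights(S, [st.group for st in stats])
    p = weights.n_traits
    A = np.zeros((p, p))
    b = np.zeros(p)
    n_used = 0
    for st, M, Sg_inv, cols in zip(
        stats, weights.scatter, weights.solve_in, weights.trait_idx
    ):
        A += st.xtx * M
        b[cols] += Sg_inv @ st.xty
        n_used += st.group.size
    try:
        c, low = scipy.linalg.cho_factor(A)
    except scipy.linalg.LinAlgError as exc:
        raise SnpSkipped(f"normal-equation matrix singular: {exc}") from exc
    beta_hat = scipy.linalg.cho_solve((c, low), b)
    cov_beta = scipy.linalg.cho_solve((c, low), np.eye(p))
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    if not np.all(np.isfinite(beta_hat)) or not np.all(np.isfinite(cov_beta)):
        raise SnpSkipped("non-finite GLS solution")
    return EffectEstimate(beta_hat=beta_hat, cov_beta=cov_beta, n_used=n_used)
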