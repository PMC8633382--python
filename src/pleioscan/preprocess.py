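"""Phenotype adjustment, variant QC, missing-pattern grouping and the
error-covariance approximation.

The test statistic downstream needs the within-subject error covariance R of
the multi-trait model. Because a single SNP explains only a small fraction of
a complex trait's variance, the covariance of covariate-adjusted, centered
phenotypes S is a close upper envelope of R (S - R-hat is positive
semi-definite), so S is computed once and reused for every SNP instead of
re-estimating residual covariances per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

#: relative eigenvalue floor used when repairing a non-PD pairwise covariance
PD_EIG_FLOOR = 1e-8


@dataclass
class AdjustedPhenotypeMatrix:
    """n x p covariate-adjusted, centered trait values with observation mask.

    ``values`` is undefined (NaN) wherever ``observed`` is False; each trait's
    observed entries have mean zero.
    """

    values: np.ndarray
    observed: np.ndarray
    trait_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


@dataclass
class ErrorCovariance:
    """p x p approximation S to the error covariance, with joint-observation
    counts per trait pair and a flag recording whether a positive-definiteness
    repair was applied."""

    S: np.ndarray
    n_pairs: np.ndarray
    repaired: bool = False


@dataclass
class PatternGroup:
    """Samples sharing one missing-value pattern (the subset of observed traits)."""

    trait_mask: np.ndarray  # boolean, length p
    member_indices: np.ndarray  # sample indices
    size: int = field(init=False)

    def __post_init__(self) -> None:
        self.size = int(len(self.member_indices))


def _check_collinear(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the redundant ones
        _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")


def adjust_phenotypes(
    raw_traits: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    transforms: dict[str, str] | Sequence[str | None] | None = None,
) -> AdjustedPhenotypeMatrix:
    """Per-trait least-squares adjustment on [intercept, covariates].

    Each trait is optionally log-transformed, regressed on the covariates over
    that trait's own observed rows, and the residuals are mean-centered. Using
    each trait's own complete rows (rather than complete cases across traits)
    maximises data use under unbalanced designs.
    """
    if isinstance(raw_traits, pd.DataFrame):
        trait_names = [str(c) for c in raw_traits.columns]
        Y = raw_traits.to_numpy(dtype=np.float64)
    else:
        Y = np.asarray(raw_traits, dtype=np.float64)
        trait_names = [f"trait{j + 1}" for j in range(Y.shape[1])]

    if covariates is None:
        C = np.empty((Y.shape[0], 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov_names = [str(c) for c in covariates.columns]
        C = covariates.to_numpy(dtype=np.float64)
    else:
        C = np.asarray(covariates, dtype=np.float64)
        cov_names = [f"cov{j + 1}" for j in range(C.shape[1])]

    if isinstance(transforms, dict):
        tf = [transforms.get(name) for name in trait_names]
    elif transforms is None:
        tf = [None] * len(trait_names)
    else:
        tf = list(transforms)

    n, p = Y.shape
    observed = np.isfinite(Y)
    values = np.full_like(Y, np.nan)

    for j in range(p):
        obs = observed[:, j]
        y = Y[obs, j]
        if tf[j] == "log":
            if np.any(y <= 0):
                raise ValueError(
                    f"trait {trait_names[j]!r}: log transform requested but "
                    "non-positive values present"
                )
            y = np.log(y)
        elif tf[j] not in (None, "identity"):
            raise ValueError(f"unknown transform {tf[j]!r} for trait {trait_names[j]!r}")

        Xj = np.column_stack([np.ones(obs.sum()), C[obs]])
        if not np.all(np.isfinite(Xj)):
            raise ValueError(
                f"trait {trait_names[j]!r}: covariates contain missing values "
                "on observed trait rows"
            )
        if obs.sum() <= Xj.shape[1]:
            raise ValueError(
                f"trait {trait_names[j]!r}: {obs.sum()} complete cases for "
                f"{Xj.shape[1]} regression coefficients"
            )
        _check_collinear(Xj, ["intercept", *cov_names])
        coef, *_ = np.linalg.lstsq(Xj, y, rcond=None)
        resid = y - Xj @ coef
        resid -= resid.mean()
        values[obs, j] = resid

    return AdjustedPhenotypeMatrix(values=values, observed=observed, trait_names=trait_names)


def variant_qc(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant A1 allele frequency and call rate from a dosage block
    (variants x samples, missing as NaN)."""
    dosage = np.atleast_2d(np.asarray(dosage, dtype=np.float64))
    nonmiss = np.isfinite(dosage)
    n_called = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dosage, axis=1) / (2.0 * np.maximum(n_called, 1))
    freq = np.where(n_called > 0, freq, np.nan)
    call_rate = n_called / dosage.shape[1]
    return freq, call_rate


def filter_variants(
    freq: np.ndarray,
    call_rate: np.ndarray,
    maf_min: float = 0.001,
    call_rate_min: float = 0.95,
) -> np.ndarray:
    """Keep mask: minor-allele frequency >= maf_min AND call rate >=
    call_rate_min (both thresholds inclusive)."""
    freq = np.asarray(freq, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
        keep = (maf >= maf_min) & (np.asarray(call_rate) >= call_rate_min)
    keep &= np.isfinite(freq)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("variant filter: dropping %d of %d variants", n_drop, keep.size)
    return keep


def find_missing_patterns(
    mask: np.ndarray, min_group_size: int = 1
) -> tuple[list[PatternGroup], int]:
    """Partition samples by their missing-value pattern.

    Returns the retained groups (each pattern with at least one observed trait
    and at least ``min_group_size`` members) and the number of samples dropped
    by the size threshold. Samples with no observed trait at all are an error.
    """
    mask = np.asarray(mask, dtype=bool)
    any_obs = mask.any(axis=1)
    if not any_obs.any():
        raise ValueError("all samples are fully missing across traits")
    idx_valid = np.flatnonzero(any_obs)
    patterns, inverse = np.unique(mask[idx_valid], axis=0, return_inverse=True)
    groups: list[PatternGroup] = []
    n_dropped = 0
    for g in range(patterns.shape[0]):
        members = idx_valid[inverse == g]
        if len(members) < min_group_size:
            n_dropped += len(members)
            continue
        groups.append(PatternGroup(trait_mask=patterns[g].copy(), member_indices=members))
    if n_dropped:
        logger.info(
            "missing-pattern grouping: dropped %d samples in groups smaller than %d",
            n_dropped,
            min_group_size,
        )
    return groups, n_dropped


def estimate_error_covariance(
    adjusted: AdjustedPhenotypeMatrix, min_pairs: int = 3
) -> ErrorCovariance:
    """Method-of-moments S from pairwise-complete products of adjusted phenotypes.

    S_jj' = sum over jointly observed samples of y_ij * y_ij' / (n_jj' - 1).
    With balanced data this is exactly the sample covariance of the adjusted
    traits. If the pairwise-complete matrix is not positive definite its
    eigenvalues are clipped at ``PD_EIG_FLOOR`` times the largest one.
    """
    Y = np.where(adjusted.observed, adjusted.values, 0.0)
    M = adjusted.observed.astype(np.float64)
    n_pairs = (M.T @ M).astype(np.int64)
    deficient = np.argwhere(n_pairs < min_pairs)
    if deficient.size:
        pairs = sorted(
            {tuple(sorted((adjusted.trait_names[i], adjusted.trait_names[j])))
             for i, j in deficient}
        )
        raise ValueError(
            f"trait pairs jointly observed in fewer than {min_pairs} samples: {pairs}"
        )
    S = (Y.T @ Y) / (n_pairs - 1.0)
    S = 0.5 * (S + S.T)
    eigvals = np.linalg.eigvalsh(S)
    repaired = False
    floor = PD_EIG_FLOOR * eigvals[-1]
    if eigvals[0] < floor:
        w, V = np.linalg.eigh(S)
        S = (V * np.maximum(w, floor)) @ V.T
        S = 0.5 * (S + S.T)
        repaired = True
        logger.warning(
            "error covariance was not positive definite; eigenvalues clipped at %.3g",
            floor,
        )
    return ErrorCovariance(S=S, n_pairs=n_pairs, repaired=repaired)
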