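"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's grouped/sufficient-statistic
code paths: the GLS oracle builds the full observation-level weighted normal
equations with an explicit dense inverse, so agreement with the grouped
engine is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brute_force_gls(x, values, observed, S):
    """Observation-level GLS: stack one row per observed (sample, trait) cell,
    build the block-diagonal error covariance sample by sample, and solve the
    weighted normal equations with explicit inverses."""
    n, p = values.shape
    rows_X, rows_y, blocks = [], [], []
    for i in range(n):
        mask = observed[i]
        if not mask.any():
            continue
        E = np.eye(p)[mask]
        rows_X.append(x[i] * E)
        rows_y.append(values[i, mask])
        blocks.append(S[np.ix_(mask, mask)])
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    Omega_inv = np.linalg.inv(scipy.linalg.block_diag(*blocks))
    A = X.T @ Omega_inv @ X
    beta = np.linalg.solve(A, X.T @ Omega_inv @ y)
    cov = np.linalg.inv(A)
    return beta, cov


def random_unbalanced_instance(rng, n_max=30, p_max=4):
    """A small random instance: centered genotype, centered trait values with
    a random missingness mask (every trait observed somewhere, every sample
    observing something), and a random well-conditioned S."""
    n = int(rng.integers(8, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    x = rng.integers(0, 3, size=n).astype(float)
    x = x - x.mean()
    if not np.any(x != 0):
        x[0] += 1.0
    values = rng.standard_normal((n, p))
    while True:
        observed = rng.random((n, p)) < 0.75
        if observed.any(axis=1).all() and observed.any(axis=0).all():
            break
    values = np.where(observed, values, np.nan)
    A = rng.standard_normal((p, p + 2))
    S = A @ A.T / (p + 2) + 0.5 * np.eye(p)
    return x, values, observed, S


def random_pd_instance(rng, p):
    """Random effect vector and well-conditioned PD covariance."""
    beta = rng.standard_normal(p)
    A = rng.standard_normal((p, p + 3))
    cov = A @ A.T / (p + 3) + 0.1 * np.eye(p)
    return beta, cov
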