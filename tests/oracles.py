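"""Independent reference computations used to check the implementation.

Everything here is deliberately written from first principles (dense numpy
formulas, explicit enumeration, Henderson's equations) and shares no code
with the package's fitting routines.
"""

from __future__ import annotations

import itertools

import numpy as np


def restricted_loglik_oracle(
    y: np.ndarray, kernels: list[np.ndarray], sigmas: np.ndarray
) -> float:
    """REML log-likelihood from the textbook formula, via slogdet and solves."""
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s, K in zip(sigmas[:-1], kernels):
        V = V + s * K
    X = np.ones((n, 1))
    Vinv = np.linalg.inv(V)
    XVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XVX) @ X.T @ Vinv
    s1, ld1 = np.linalg.slogdet(V)
    s2, ld2 = np.linalg.slogdet(XVX)
    assert s1 > 0 and s2 > 0
    return float(-0.5 * (ld1 + ld2 + y @ P @ y))


def grid_search_reml(
    y: np.ndarray,
    kernels: list[np.ndarray],
    n_points: int = 13,
    span: float = 30.0,
) -> tuple[np.ndarray, float]:
    """Brute-force REML: best point of a log-spaced variance grid."""
    vy = y.var()
    axis = np.geomspace(vy / span, vy * 3, n_points)
    best, best_ll = None, -np.inf
    for combo in itertools.product(axis, repeat=len(kernels) + 1):
        ll = restricted_loglik_oracle(y, kernels, np.array(combo))
        if ll > best_ll:
            best, best_ll = np.array(combo), ll
    return best, best_ll


def henderson_blup(
    y: np.ndarray,
    kernels: list[np.ndarray],
    sigmas: np.ndarray,
    jitter: float = 1e-10,
) -> tuple[float, list[np.ndarray]]:
    """Mixed-model-equation solve for the intercept model at fixed variances.

    Henderson's coefficient matrix with K⁻¹ σ_e²/σ_i² blocks; a tiny jitter
    keeps near-singular kernels invertible.
    """
    n = len(y)
    se2 = sigmas[-1]
    X = np.ones((n, 1))
    Z = [np.eye(n) for _ in kernels]
    Kinvs = [
        np.linalg.inv(K + jitter * np.trace(K) / n * np.eye(n)) for K in kernels
    ]
    blocks = [[X.T @ X] + [X.T @ Zi for Zi in Z]]
    for i, Zi in enumerate(Z):
        row = [Zi.T @ X]
        for j, Zj in enumerate(Z):
            ZZ = Zi.T @ Zj
            if i == j:
                ZZ = ZZ + Kinvs[i] * se2 / sigmas[i]
            row.append(ZZ)
        blocks.append(row)
    C = np.block(blocks)
    rhs = np.concatenate([X.T @ y] + [Zi.T @ y for Zi in Z])
    sol = np.linalg.solve(C, rhs)
    mu = float(sol[0])
    effects = [sol[1 + i * n : 1 + (i + 1) * n] for i in range(len(kernels))]
    return mu, effects


def one_way_reml_closed_form(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Balanced one-way random-effects REML: ANOVA estimators.

    For balanced data REML coincides with the ANOVA method when the
    between-group estimate is positive: σ_e² = MSW, σ_g² = (MSB − MSW)/r.
    """
    labels = np.unique(groups)
    r = len(y) // len(labels)
    means = np.array([y[groups == g].mean() for g in labels])
    msb = r * ((means - y.mean()) ** 2).sum() / (len(labels) - 1)
    msw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    msw /= len(labels) * (r - 1)
    return (msb - msw) / r, msw


def conditional_mean_prediction(
    y: np.ndarray,
    Ka_tt: np.ndarray,
    Kaa_tt: np.ndarray,
    Ka_st: np.ndarray,
    Kaa_st: np.ndarray,
    sigmas: np.ndarray,
    mu: float,
) -> np.ndarray:
    """Joint-Gaussian conditional mean of shelf genetic values given test y.

    Equivalent to refitting the union mixed model with shelf phenotypes
    missing: ĝ(shelf) = Cov(g_shelf, y_test) V⁻¹ (y − μ).
    """
    sa2, saa2, se2 = sigmas
    n = len(y)
    V = sa2 * Ka_tt + saa2 * Kaa_tt + se2 * np.eye(n)
    alpha = np.linalg.solve(V, y - mu)
    return mu + (sa2 * Ka_st + saa2 * Kaa_st) @ alpha
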