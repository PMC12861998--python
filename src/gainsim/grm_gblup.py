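"""Genomic relationship matrices and two-kernel GBLUP via NR-REML.

The prediction model is

    y = Xβ + Z_a a + Z_aa aa + ε,
    a ~ N(0, G_a σ_a²),  aa ~ N(0, G_aa' σ_aa²),  ε ~ N(0, I σ_e²),

with X a single intercept column. G_a is the VanRaden additive relationship
matrix built from the centered marker matrix M (dosages -1/0/1), normalized
so the mean diagonal equals 1; G_aa' is the trace-normalized Hadamard square
of G_a, the standard additive×additive epistatic kernel.

Variance components are estimated by restricted maximum likelihood using
Newton–Raphson on log-variance parameters (with a Fisher-scoring fallback and
boundary clamping), BLUPs come from the mixed-model solution at the REML
optimum, and predictions for unphenotyped (shelf) individuals are obtained by
kriging: projecting the fitted test-set BLUPs through the between-group
kinship blocks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve, pinvh

from .genome_founders import ConfigurationError, HaplotypePopulation

__all__ = [
    "KernelSet",
    "FitResult",
    "code_and_center",
    "additive_grm",
    "epistatic_grm",
    "build_kernels",
    "fit_reml",
    "restricted_loglik",
    "project_to_shelf",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class KernelSet:
    """Centered marker matrix and the relationship matrices derived from it."""

    M: np.ndarray  # (n, m) centered dosages
    Ga: np.ndarray  # (n, n) additive GRM, mean diagonal 1
    Gaa: np.ndarray  # (n, n) raw Hadamard square
    Gaa_norm: np.ndarray  # (n, n) trace-normalized epistatic GRM
    marker_means: np.ndarray  # (m,) dosage mean per marker
    ids: np.ndarray | None = None

    def export(self, path: str, which: str = "Ga") -> None:
        """Dense plain-text export with individual-id headers, for audit."""
        K = getattr(self, which)
        ids = self.ids if self.ids is not None else np.arange(K.shape[0])
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(map(str, ids)) + "\n")
            for i, row in zip(ids, K):
                fh.write(str(i) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


@dataclasses.dataclass
class FitResult:
    sigma_a2: float
    sigma_aa2: float
    sigma_e2: float
    mu: float
    blup_a: np.ndarray
    blup_aa: np.ndarray
    converged: bool
    n_iterations: int
    loglik: float

    @property
    def total_blup(self) -> np.ndarray:
        return self.blup_a + self.blup_aa


def code_and_center(
    pop: HaplotypePopulation, snp_subset: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Centered marker matrix M = G − 1·x̄ᵀ from -1/0/1 genotype codes."""
    if snp_subset is None:
        snp_subset = pop.gmap.snp_indices
    snp_subset = np.asarray(snp_subset)
    if snp_subset.size == 0:
        raise ConfigurationError("empty SNP set")
    G = pop.dosage()[:, snp_subset].astype(np.float64)
    xbar = G.mean(axis=0)
    return G - xbar, xbar


def additive_grm(M: np.ndarray, normalizer: str = "trace") -> np.ndarray:
    """VanRaden-style additive GRM from the centered marker matrix.

    ``normalizer="trace"`` uses s = tr(MMᵀ)/n so mean(diag) = 1;
    ``normalizer="2pq"`` uses the classical 2Σp_k q_k denominator. Kernel
    scaling is absorbed by σ_a², so the two are likelihood-equivalent.
    """
    MMt = M @ M.T
    n = M.shape[0]
    if normalizer == "trace":
        s = np.trace(MMt) / n
    elif normalizer == "2pq":
        p = (M - M.min(axis=0)).mean(axis=0) / 2.0  # mean shifted to [0, 2]
        s = 2.0 * np.sum(p * (1 - p))
    else:
        raise ConfigurationError(f"unknown normalizer {normalizer}")
    if s <= 0:
        raise ConfigurationError("marker matrix carries no variance")
    return MMt / s


def epistatic_grm(Ga: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hadamard square of G_a, raw and trace-normalized to mean diagonal 1."""
    Gaa = Ga * Ga
    n = Ga.shape[0]
    return Gaa, Gaa / (np.trace(Gaa) / n)


def build_kernels(
    pop: HaplotypePopulation, snp_subset: np.ndarray | None = None
) -> KernelSet:
    M, xbar = code_and_center(pop, snp_subset)
    Ga = additive_grm(M)
    Gaa, Gaa_norm = epistatic_grm(Ga)
    return KernelSet(M=M, Ga=Ga, Gaa=Gaa, Gaa_norm=Gaa_norm, marker_means=xbar, ids=pop.ids.copy())


def _safe_cho_factor(V: np.ndarray):
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.mean(np.diag(V))
        warnings.warn("singular coefficient matrix; applying ridge fallback")
        return cho_factor(V + ridge * np.eye(V.shape[0]), lower=True)


def restricted_loglik(
    y: np.ndarray, kernels: list[np.ndarray], sigmas: np.ndarray
) -> float:
    """Restricted log-likelihood of the intercept model at given variances.

    ``kernels`` excludes the residual; ``sigmas`` is (σ² per kernel..., σ_e²).
    """
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s, K in zip(sigmas[:-1], kernels):
        V = V + s * K
    c = _safe_cho_factor(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    X = np.ones((n, 1))
    VinvX = cho_solve(c, X)
    XVX = X.T @ VinvX
    Vinvy = cho_solve(c, y)
    beta = np.linalg.solve(XVX, X.T @ Vinvy)
    resid = y - (X @ beta).ravel()
    Py = cho_solve(c, resid)  # V⁻¹(y − Xβ̂) equals P y
    return float(-0.5 * (logdetV + np.log(np.linalg.det(XVX)) + resid @ Py))


def _reml_state(y, X, kernels, sigmas):
    """P, Py, gradient, expected and observed information at one point."""
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s, K in zip(sigmas[:-1], kernels):
        V = V + s * K
    c = _safe_cho_factor(V)
    Vinv = cho_solve(c, np.eye(n))
    VinvX = Vinv @ X
    XVX = X.T @ VinvX
    P = Vinv - VinvX @ np.linalg.solve(XVX, VinvX.T)
    Py = P @ y
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    ll = -0.5 * (logdetV + np.log(np.linalg.det(XVX)) + y @ Py)

    comps = list(kernels) + [None]  # None = residual identity kernel
    PG = [P @ K if K is not None else P for K in comps]
    KPy = [K @ Py if K is not None else Py for K in comps]
    k = len(comps)
    grad = np.empty(k)
    fisher = np.empty((k, k))
    obs = np.empty((k, k))
    for i in range(k):
        grad[i] = -0.5 * (np.trace(PG[i]) - Py @ KPy[i])
        for j in range(i, k):
            tij = float(np.sum(PG[i] * PG[j].T))
            qij = float(KPy[i] @ (P @ KPy[j]))
            fisher[i, j] = fisher[j, i] = 0.5 * tij
            # Hessian of the restricted loglik wrt (σ_i², σ_j²)
            obs[i, j] = obs[j, i] = 0.5 * tij - qij
    return ll, grad, fisher, obs, P, Py, Vinv, XVX


def fit_reml(
    y: np.ndarray,
    Ga: np.ndarray,
    Gaa_norm: np.ndarray | None,
    tol: float = 1e-6,
    max_iter: int = 80,
    floor_frac: float = 1e-8,
) -> FitResult:
    """Newton–Raphson REML for the one- or two-kernel intercept model.

    Optimization is on θ = log σ² (which enforces non-negativity), using the
    observed Hessian with a Fisher-scoring fallback and step halving;
    components are clamped at ``floor_frac × Var(y)``. Non-convergence within
    ``max_iter`` flags the result rather than raising.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    kernels = [np.asarray(Ga, dtype=np.float64)]
    if Gaa_norm is not None:
        kernels.append(np.asarray(Gaa_norm, dtype=np.float64))
    for K in kernels:
        if K.shape != (n, n):
            raise ConfigurationError("kernel dimension does not match y")
    X = np.ones((n, 1))
    vy = float(y.var())
    if vy <= 0:
        raise ConfigurationError("phenotype vector has zero variance")
    floor = floor_frac * vy
    k = len(kernels) + 1

    sigmas = np.full(k, vy / k)
    theta = np.log(sigmas)
    log_floor = np.log(floor)
    ll, grad, fisher, obs, P, Py, Vinv, XVX = _reml_state(y, X, kernels, sigmas)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = np.exp(theta)
        # chain rule to θ = log σ²
        g_t = grad * s
        H_t = obs * np.outer(s, s) + np.diag(g_t)
        B = -H_t  # negated Hessian: positive definite near an interior optimum
        at_floor = (theta <= log_floor + 1e-12) & (g_t < 0)
        step = None
        try:
            cB = cho_factor(B)
            step = cho_solve(cB, g_t)
        except np.linalg.LinAlgError:
            pass
        if step is None or not np.all(np.isfinite(step)):
            F_t = fisher * np.outer(s, s) + 1e-12 * np.eye(k)
            step = np.linalg.solve(F_t, g_t)
        step = np.where(at_floor, 0.0, step)
        step = np.clip(step, -4.0, 4.0)

        improved = False
        log_ceiling = np.log(vy) + 30.0  # overflow guard; never active in practice
        for _ in range(25):
            cand = np.clip(theta + step, log_floor, log_ceiling)
            out = _reml_state(y, X, kernels, np.exp(cand))
            if np.isfinite(out[0]) and out[0] >= ll - 1e-12:
                theta = cand
                new_ll = out[0]
                ll_prev = ll
                ll, grad, fisher, obs, P, Py, Vinv, XVX = out
                improved = True
                break
            step = step / 2.0
        if not improved:
            break
        if abs(ll - ll_prev) < tol:
            converged = True
            break

    sigmas = np.exp(theta)
    mu = float(np.linalg.solve(XVX, X.T @ (Vinv @ y)).ravel()[0])
    blups = [s_i * (K @ Py) for s_i, K in zip(sigmas[:-1], kernels)]
    blup_a = blups[0]
    blup_aa = blups[1] if len(blups) > 1 else np.zeros(n)
    return FitResult(
        sigma_a2=float(sigmas[0]),
        sigma_aa2=float(sigmas[1]) if len(kernels) > 1 else 0.0,
        sigma_e2=float(sigmas[-1]),
        mu=mu,
        blup_a=blup_a,
        blup_aa=blup_aa,
        converged=converged,
        n_iterations=it,
        loglik=float(ll),
    )


def project_to_shelf(
    fit: FitResult,
    Ka_cross: np.ndarray,
    Kaa_cross: np.ndarray | None,
    Ka_test: np.ndarray,
    Kaa_test: np.ndarray | None,
    rcond: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kriging projection of fitted test-set BLUPs onto shelf individuals.

    ``K*_cross`` are the test×shelf blocks and ``K*_test`` the test×test
    blocks of kernels built on the union set. Per component c,
    ĝ_c(shelf) = K_cross,cᵀ K_test,c⁻ ĝ_c(test) with a pseudo-inverse;
    the returned prediction is ŷ = mu + ĝ_a + ĝ_aa.
    """
    n_test = Ka_test.shape[0]
    if Ka_cross.shape[0] != n_test:
        raise ConfigurationError("cross-kernel rows must match the test set")

    def _project(K_cross, K_test, g_test):
        Kinv = pinvh(K_test, rtol=rcond)
        cond = np.linalg.cond(K_test)
        if cond > 1.0 / rcond:
            logger.info("ill-conditioned test kernel (cond=%.3e); pseudo-inverse", cond)
        return K_cross.T @ (Kinv @ g_test)

    g_a = _project(Ka_cross, Ka_test, fit.blup_a)
    if Kaa_cross is not None and Kaa_test is not None:
        g_aa = _project(Kaa_cross, Kaa_test, fit.blup_aa)
    else:
        g_aa = np.zeros(Ka_cross.shape[1])
    return fit.mu + g_a + g_aa, g_a, g_aa
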