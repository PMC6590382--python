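"""Bayesian reduced-rank regression (BRRR) with multiplicative-Gamma shrinkage.

Model, for a column-centered phenotype Y (N x P) and covariates X (N x M'):

    Y = (X Psi + Omega) Gamma + E

where Psi (M' x K) maps covariates to a K-dimensional latent space,
Omega (N x K) is latent-space noise, Gamma (K x P) projects the latent
space onto the observed features, and E is i.i.d. Gaussian observation
noise with fixed SD sigma_e.  The product beta = Psi Gamma is a rank-K
regression coefficient matrix.

Shrinkage prior: columns psi_:k and rows gamma_k,: are N(0, tau_k^-1 I)
with tau_k = prod_{l<=k} delta_l, delta_1 ~ Gamma(10, 1) and
delta_{l>1} ~ Gamma(4.1, 1), so later components are shrunk harder and
component importance is ordered.  Omega entries have fixed prior SD
omega_scale * tau_k^-1; sigma_e is fixed, not sampled.

Inference is Gibbs sampling from the standard conjugate full conditionals,
started from an informed initialization in which the covariates explain
maximal variance (ridge-stabilized least squares followed by a truncated
SVD of the fitted values, components ordered by singular value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla

from ._rng import substream
from .cohort import SpectralPhenotype

__all__ = [
    "BRRRConfig",
    "BRRRPosterior",
    "init_reduced_rank",
    "fit",
    "ptve",
    "coefficient_matrix",
    "latent_embed",
    "convergence_diagnostic",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BRRRConfig:
    """Sampler settings.

    K : number of latent components (rank of beta).
    n_iter / burn_in : Gibbs iterations and discarded prefix.
    sigma_e : fixed observation-noise SD.
    omega_scale : multiplier on tau_k^-1 giving the latent-noise prior SD.
    delta1_* / delta_* : Gamma(shape, rate) hyperpriors of the shrinkage
        multipliers for the first and later components.
    """

    K: int = 6
    n_iter: int = 500
    burn_in: int = 250
    sigma_e: float = 0.1
    omega_scale: float = 1e-6
    delta1_shape: float = 10.0
    delta1_rate: float = 1.0
    delta_shape: float = 4.1
    delta_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        for name in ("sigma_e", "omega_scale", "delta1_shape", "delta1_rate",
                     "delta_shape", "delta_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_seed(self, seed: int) -> "BRRRConfig":
        return replace(self, seed=int(seed))


@dataclass
class BRRRPosterior:
    """Post-burn-in Gibbs samples and posterior means for one fitted model."""

    psi_samples: np.ndarray      # (S, M', K)
    gamma_samples: np.ndarray    # (S, K, P)
    omega_samples: np.ndarray    # (S, N, K)
    delta_samples: np.ndarray    # (S, K)
    col_means: np.ndarray        # centering vector applied to Y
    config: BRRRConfig

    @property
    def n_samples(self) -> int:
        return self.psi_samples.shape[0]

    @property
    def tau_samples(self) -> np.ndarray:
        """Per-sample precisions tau_k = prod_{l<=k} delta_l (exact cumprod)."""
        return np.cumprod(self.delta_samples, axis=1)

    @property
    def psi_mean(self) -> np.ndarray:
        return self.psi_samples.mean(axis=0)

    @property
    def gamma_mean(self) -> np.ndarray:
        return self.gamma_samples.mean(axis=0)

    @property
    def omega_mean(self) -> np.ndarray:
        return self.omega_samples.mean(axis=0)


def _as_matrix(Y: SpectralPhenotype | np.ndarray) -> np.ndarray:
    if isinstance(Y, SpectralPhenotype):
        return Y.values
    return np.asarray(Y, dtype=float)


def init_reduced_rank(
    Y: SpectralPhenotype | np.ndarray,
    X: np.ndarray,
    K: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Informed initialization: covariates explain maximal variance in Y.

    Ridge-stabilized least squares B = argmin ||Y - X B||^2, then a
    rank-K truncated SVD of the fitted values X B = U S V^T gives
    Psi0 = B V_K and Gamma0 = V_K^T, with components ordered by decreasing
    singular value (each explaining less variance than the previous one).
    Y is used as given; the sampler passes column-centered data.
    """
    Yc = _as_matrix(Y)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != Yc.shape[0]:
        raise ValueError("X must be 2-D with one row per phenotype row")
    XtX = X.T @ X
    lam = 1e-8 * np.trace(XtX)
    B = np.linalg.solve(XtX + lam * np.eye(X.shape[1]), X.T @ Yc)
    fitted = X @ B
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    achievable = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if achievable == 0:
        # degenerate: no structure; keep K arbitrary directions
        achievable = min(K, Vt.shape[0])
    if K > achievable:
        warnings.warn(
            f"requested K={K} exceeds achievable rank {achievable}; reducing",
            RuntimeWarning,
        )
        K = achievable
    VK = Vt[:K].T
    return B @ VK, VK.T


def fit(
    Y: SpectralPhenotype | np.ndarray,
    X: np.ndarray,
    config: BRRRConfig,
) -> BRRRPosterior:
    """Gibbs sampling for the reduced-rank model; deterministic given the seed.

    Y is column-centered internally.  sigma_e and the Omega scale are fixed
    (not sampled); Psi, Gamma, Omega and the shrinkage multipliers delta are
    drawn from their conjugate full conditionals.
    """
    Ymat = _as_matrix(Y)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(Ymat)) or not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    if X.ndim != 2 or X.shape[0] != Ymat.shape[0]:
        raise ValueError("X must be 2-D with one row per phenotype row")
    N, P = Ymat.shape
    M = X.shape[1]
    if config.K > N:
        raise ValueError(f"K={config.K} exceeds N={N}")
    col_means = Ymat.mean(axis=0)
    Yc = Ymat - col_means
    y2 = float(np.sum(Yc * Yc))

    Psi, Gamma = init_reduced_rank(Yc, X, config.K)
    K = Psi.shape[1]  # may have been reduced
    rng = substream(config.seed, "gibbs")
    s2 = config.sigma_e**2

    # shrinkage multipliers start at prior means
    delta = np.full(K, config.delta_shape / config.delta_rate)
    delta[0] = config.delta1_shape / config.delta1_rate
    tau = np.cumprod(delta)
    Omega = np.zeros((N, K))

    # eigendecomposition of X'X makes each Psi-column draw O(M^2)
    XtX = X.T @ X
    evals, Q = np.linalg.eigh(XtX)
    evals = np.clip(evals, 0.0, None)

    n_keep = config.n_iter - config.burn_in
    psi_s = np.empty((n_keep, M, K))
    gamma_s = np.empty((n_keep, K, P))
    omega_s = np.empty((n_keep, N, K))
    delta_s = np.empty((n_keep, K))

    XPsi = X @ Psi
    for it in range(config.n_iter):
        # --- Gamma | rest : per-column Gaussian, shared K x K precision
        Z = XPsi + Omega
        prec = Z.T @ Z / s2 + np.diag(tau)
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Z.T @ Yc / s2)
        noise = sla.solve_triangular(L, rng.standard_normal((K, P)), lower=True, trans="T")
        Gamma = mean + noise

        # --- Psi | rest : column-wise Gaussian via eigenbasis of X'X
        Resid = Yc - (XPsi + Omega) @ Gamma
        for k in range(K):
            gk = Gamma[k]
            g2 = float(gk @ gk)
            rk = Resid @ gk + XPsi[:, k] * g2  # (Resid + outer(X psi_k, gk)) @ gk
            a = g2 / s2
            d = a * evals + tau[k]
            b = Q.T @ (X.T @ rk / s2)
            mean_k = Q @ (b / d)
            psi_k = mean_k + Q @ (rng.standard_normal(M) / np.sqrt(d))
            new_col = X @ psi_k
            Resid -= np.outer(new_col - XPsi[:, k], gk)
            XPsi[:, k] = new_col
            Psi[:, k] = psi_k

        # --- Omega | rest : row-wise Gaussian, shared K x K precision
        R = Resid + Omega @ Gamma  # Yc - X Psi Gamma
        omega_var = (config.omega_scale / tau) ** 2
        precO = Gamma @ Gamma.T / s2 + np.diag(1.0 / omega_var)
        LO = np.linalg.cholesky(precO)
        meanO = np.linalg.solve(precO, Gamma @ R.T / s2).T
        noiseO = sla.solve_triangular(LO, rng.standard_normal((K, N)), lower=True, trans="T").T
        Omega = meanO + noiseO

        # --- delta | Psi, Gamma : conjugate multiplicative-Gamma updates
        ss = np.sum(Psi * Psi, axis=0) + np.sum(Gamma * Gamma, axis=1)  # per component
        n_par = M + P
        for l in range(K):
            shape = (config.delta1_shape if l == 0 else config.delta_shape) \
                + 0.5 * n_par * (K - l)
            d_excl = delta.copy()
            d_excl[l] = 1.0
            tau_excl = np.cumprod(d_excl)
            rate = (config.delta1_rate if l == 0 else config.delta_rate) \
                + 0.5 * float(np.sum(tau_excl[l:] * ss[l:]))
            delta[l] = rng.gamma(shape, 1.0 / rate)
            tau = np.cumprod(delta)

        if it >= config.burn_in:
            j = it - config.burn_in
            psi_s[j] = Psi
            gamma_s[j] = Gamma
            omega_s[j] = Omega
            delta_s[j] = delta

    cfg = config if K == config.K else replace(config, K=K)
    return BRRRPosterior(
        psi_samples=psi_s,
        gamma_samples=gamma_s,
        omega_samples=omega_s,
        delta_samples=delta_s,
        col_means=col_means,
        config=cfg,
    )


def ptve(
    posterior: BRRRPosterior,
    Y: SpectralPhenotype | np.ndarray,
    X: np.ndarray,
    covariate_subset: np.ndarray | list[int] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Proportion of total variance explained by a covariate subset.

    Per post-burn-in sample s:

        PTVE_s = || X[:, sub] Psi_s[sub, :] Gamma_s ||_F^2 / || Y_c ||_F^2

    Returns (mean, SD, per-sample trace); the posterior SD is the standard
    error used downstream for significance.
    """
    Ymat = _as_matrix(Y)
    Yc = Ymat - Ymat.mean(axis=0, keepdims=True)
    y2 = float(np.sum(Yc * Yc))
    X = np.asarray(X, dtype=float)
    if covariate_subset is None:
        covariate_subset = np.arange(X.shape[1])
    sub = np.asarray(covariate_subset, dtype=int)
    if sub.size == 0:
        raise ValueError("covariate subset must be non-empty")
    Xs = X[:, sub]
    S = posterior.n_samples
    trace = np.empty(S)
    if sub.size == 1:
        g2 = float(Xs[:, 0] @ Xs[:, 0])
        for s in range(S):
            row = posterior.psi_samples[s, sub[0]] @ posterior.gamma_samples[s]
            trace[s] = g2 * float(row @ row) / y2
    else:
        for s in range(S):
            A = Xs @ posterior.psi_samples[s][sub] @ posterior.gamma_samples[s]
            trace[s] = float(np.sum(A * A)) / y2
    sd = float(trace.std(ddof=1)) if S > 1 else 0.0
    return float(trace.mean()), sd, trace


def coefficient_matrix(posterior: BRRRPosterior, method: str = "product_of_means") -> np.ndarray:
    """Posterior regression coefficient matrix beta = Psi Gamma.

    The model constrains beta to rank K; the default point estimate is the
    product of the posterior means, which preserves that rank exactly.
    ``method='mean_of_products'`` instead averages the per-sample products
    Psi_s Gamma_s (a Monte-Carlo estimate of E[Psi Gamma] whose numerical
    rank exceeds K by sampling noise).
    """
    if posterior.n_samples < 1:
        raise ValueError("posterior has no samples")
    if method == "product_of_means":
        return posterior.psi_mean @ posterior.gamma_mean
    if method == "mean_of_products":
        S = posterior.n_samples
        beta = np.zeros((posterior.psi_samples.shape[1], posterior.gamma_samples.shape[2]))
        for s in range(S):
            beta += posterior.psi_samples[s] @ posterior.gamma_samples[s]
        return beta / S
    raise ValueError(f"unknown method {method!r}")


def latent_embed(
    Y: SpectralPhenotype | np.ndarray,
    Gamma: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Latent coordinates Y_c Gamma^+ via the right pseudo-inverse of Gamma.

    Gamma^+ = Gamma^T (Gamma Gamma^T)^-1 for full row rank; the result
    satisfies (Y Gamma^+) Gamma = orthogonal projection of Y_c onto the
    row space of Gamma.  ``center`` defaults to Y's own column means (pass
    training means when embedding held-out rows).
    """
    Ymat = _as_matrix(Y)
    Gamma = np.asarray(Gamma, dtype=float)
    if center is None:
        center = Ymat.mean(axis=0)
    Yc = Ymat - center
    GGt = Gamma @ Gamma.T
    cond = np.linalg.cond(GGt)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("Gamma is rank-deficient; using truncated-SVD pseudo-inverse",
                      RuntimeWarning)
        return Yc @ np.linalg.pinv(Gamma)
    return Yc @ Gamma.T @ np.linalg.inv(GGt)


@dataclass
class TraceSummary:
    trace: np.ndarray
    running_mean: np.ndarray
    split_half_diff: float
    converged: bool
    tol: float


def convergence_diagnostic(
    posterior: BRRRPosterior,
    Y: SpectralPhenotype | np.ndarray,
    X: np.ndarray,
    covariate_subset: np.ndarray | None = None,
    tol: float = 0.005,
) -> TraceSummary:
    """Stability of the PTVE trace across retained samples.

    Flags non-convergence when the split-half means differ by more than
    ``tol``, or when the trace dispersion exceeds 10x ``tol`` (an
    oscillating chain has equal split-half means but huge spread).
    """
    if posterior.n_samples < 2:
        raise ValueError("need at least two retained samples")
    _, _, trace = ptve(posterior, Y, X, covariate_subset)
    half = trace.size // 2
    diff = float(abs(trace[:half].mean() - trace[half:].mean()))
    running = np.cumsum(trace) / np.arange(1, trace.size + 1)
    return TraceSummary(
        trace=trace,
        running_mean=running,
        split_half_diff=diff,
        converged=diff <= tol and float(trace.std()) <= 10 * tol,
        tol=tol,
    )
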