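"""Empirical-Bayes local false discovery rates for PTVE effects.

Observed effects x_s (PTVE minus a null offset) with standard errors s_s
are modelled as draws from a mixture prior

    g = pi_0 delta_0 + sum_j pi_j Uniform(0, a_j),

a non-negative unimodal family on a fixed grid of half-uniform scales,
convolved with Gaussian measurement noise N(0, s_s^2).  Mixture weights
are estimated by maximum (penalized) marginal likelihood via EM; the
local false discovery rate of effect s is the posterior probability of
the point-mass-at-zero component.  A mild Dirichlet penalty on the null
weight keeps the estimate conservative when the data cannot distinguish
small effects from none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["MixtureFit", "fit_halfuniform_mixture", "lfdr_from_effects"]


@dataclass
class MixtureFit:
    pi: np.ndarray           # mixture weights, pi[0] is the null point mass
    grid: np.ndarray         # half-uniform upper limits a_j (grid[0]=0 placeholder)
    loglik_trace: np.ndarray
    lfdr: np.ndarray
    converged: bool

    @property
    def pi0(self) -> float:
        return float(self.pi[0])

    def lfdr_at(self, x: np.ndarray, se: np.ndarray | float) -> np.ndarray:
        """Posterior null probability of new effects under the fitted mixture."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        se = np.broadcast_to(np.asarray(se, dtype=float), x.shape)
        L = _component_likelihoods(x, se, self.grid)
        dens = L @ self.pi
        return np.clip(self.pi[0] * L[:, 0] / dens, 0.0, 1.0)


def _component_likelihoods(x: np.ndarray, se: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """L[i, j] = marginal density of x_i under component j.

    Component 0 is the point mass at zero (density N(x; 0, se^2)); component
    j>0 is Uniform(0, a_j) convolved with N(0, se^2):
        (Phi(x/se) - Phi((x - a_j)/se)) / a_j.
    """
    n, J = x.size, grid.size
    L = np.empty((n, J))
    L[:, 0] = norm.pdf(x, loc=0.0, scale=se)
    for j in range(1, J):
        a = grid[j]
        L[:, j] = (norm.cdf(x / se) - norm.cdf((x - a) / se)) / a
    return np.clip(L, 1e-300, None)


def _default_grid(x: np.ndarray, se: np.ndarray) -> np.ndarray:
    a_min = max(float(np.min(se)) / 10.0, 1e-12)
    a_max = max(2.0 * float(np.max(np.abs(x))), 2 * a_min)
    grid = [0.0]
    a = a_min
    while a < a_max:
        grid.append(a)
        a *= np.sqrt(2.0)
    grid.append(a)
    return np.asarray(grid)


def fit_halfuniform_mixture(
    x: np.ndarray,
    se: np.ndarray,
    penalty: float = 10.0,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> MixtureFit:
    """EM fit of the null + half-uniform mixture; returns weights and LFDRs.

    ``penalty`` adds a Dirichlet pseudo-count on the null component
    (penalized likelihood, favoring the null when weights are ambiguous).
    Raises if EM fails to converge within ``max_iter`` iterations.
    """
    x = np.asarray(x, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    grid = _default_grid(x, se)
    L = _component_likelihoods(x, se, grid)
    n, J = L.shape
    pi = np.full(J, 1.0 / J)
    pen = np.zeros(J)
    pen[0] = max(penalty - 1.0, 0.0)
    lls = []
    converged = False
    for it in range(max_iter):
        dens = L @ pi
        ll = float(np.sum(np.log(dens)) + pen[0] * np.log(max(pi[0], 1e-300)))
        lls.append(ll)
        resp = L * pi
        resp /= resp.sum(axis=1, keepdims=True)
        counts = resp.sum(axis=0) + pen
        pi = counts / counts.sum()
        if it > 0 and abs(lls[-1] - lls[-2]) < tol * (1 + abs(lls[-2])):
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"LFDR mixture EM did not converge in {max_iter} iterations "
            f"(last log-likelihood change {lls[-1] - lls[-2]:.3e})"
        )
    dens = L @ pi
    lfdr = np.clip(pi[0] * L[:, 0] / dens, 0.0, 1.0)
    return MixtureFit(
        pi=pi,
        grid=grid,
        loglik_trace=np.asarray(lls),
        lfdr=lfdr,
        converged=converged,
    )


def lfdr_from_effects(ptve: np.ndarray, ptve_sd: np.ndarray, null_offset: float,
                      **kwargs) -> MixtureFit:
    """Convenience wrapper: effects are PTVEs re-centered by the null offset."""
    x = np.asarray(ptve, dtype=float) - null_offset
    return fit_halfuniform_mixture(x, np.asarray(ptve_sd, dtype=float), **kwargs)
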