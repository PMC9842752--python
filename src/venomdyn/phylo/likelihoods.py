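"""Model covariances and log-likelihoods for Gaussian trait models.

Under BM, OU (root at the optimum) and EB, tip values are multivariate
normal with a mean vector ``a * 1`` and a covariance determined by the
shared-path matrix ``s_ij`` of the tree:

* BM:  ``V_ij = sigma2 * s_ij``
* OU:  ``V_ij = sigma2/(2 alpha) * exp(-2 alpha (T - s_ij)) * (1 - exp(-2 alpha s_ij))``
* EB:  ``V_ij = sigma2 * (exp(r s_ij) - 1) / r``  (-> ``sigma2 * s_ij`` as r -> 0)

The BM likelihood is evaluated in O(n) by Felsenstein's pruning
(contrasts) algorithm; OU and EB use a dense Cholesky factorization of
the model covariance, which is cheap at comparative-study sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from venomdyn.core_io import Phylogeny
from venomdyn.errors import NotUltrametricError

_LOG2PI = np.log(2.0 * np.pi)

__all__ = ["bm_loglik", "ou_covariance", "eb_covariance", "mvn_loglik", "bm_prune"]


def bm_prune(trait: np.ndarray, tree: Phylogeny) -> tuple[float, float, float]:
    """One pruning pass for BM with unit rate.

    Returns ``(ss, logdet, mu_root)`` where ``ss`` is the quadratic form
    ``(x - mu_root 1)' C^-1 (x - mu_root 1)``, ``logdet`` is ``log|C|``
    and ``mu_root`` is the GLS root estimate, all for ``sigma2 = 1``.
    Contrasts between successive children are folded in sequentially, so
    multifurcations are handled.
    """
    x = np.asarray(trait, float)
    mu = np.empty(tree.n_nodes)
    v = np.empty(tree.n_nodes)  # extra variance above the node
    ss = 0.0
    logdet = 0.0
    for nd in tree.postorder():
        if tree.is_tip(nd):
            mu[nd] = x[nd]
            v[nd] = tree.branch_lengths[nd]
            continue
        kids = tree.children[nd]
        m, vv = mu[kids[0]], v[kids[0]]
        for k in kids[1:]:
            m2, v2 = mu[k], v[k]
            tot = vv + v2
            ss += (m - m2) ** 2 / tot
            logdet += np.log(tot)
            m = (m * v2 + m2 * vv) / tot
            vv = vv * v2 / tot
        mu[nd] = m
        v[nd] = vv + tree.branch_lengths[nd]
    root = tree.root
    # the factorization C = product of contrast variances x root variance
    logdet += np.log(v[root]) if v[root] > 0 else 0.0
    return ss, logdet, float(mu[root])


def bm_loglik(trait: np.ndarray, tree: Phylogeny, sigma2: float, root: float) -> float:
    """Log-likelihood of tips under BM with rate ``sigma2`` and root state ``root``."""
    if sigma2 <= 0:
        warnings.warn("bm_loglik: sigma2 <= 0, returning -inf")
        return -np.inf
    n = tree.n_tips
    ss, logdet, mu_root = bm_prune(trait, tree)
    v_root = _root_variance(tree)
    ss_total = ss + (mu_root - root) ** 2 / v_root if v_root > 0 else ss
    return -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + ss_total / sigma2)


def _root_variance(tree: Phylogeny) -> float:
    """Variance (unit rate) of the GLS root mean: (1' C^-1 1)^-1, via pruning."""
    v = np.empty(tree.n_nodes)
    for nd in tree.postorder():
        if tree.is_tip(nd):
            v[nd] = tree.branch_lengths[nd]
            continue
        kids = tree.children[nd]
        vv = v[kids[0]]
        for k in kids[1:]:
            vv = vv * v[k] / (vv + v[k])
        v[nd] = vv + tree.branch_lengths[nd]
    return float(v[tree.root])


def ou_covariance(tree: Phylogeny, sigma2: float, alpha: float) -> np.ndarray:
    """OU tip covariance with the root fixed at the optimum (non-stationary)."""
    if not tree.is_ultrametric():
        raise NotUltrametricError("OU covariance requires an ultrametric tree")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = tree.shared_path_matrix()
    T = tree.height
    return sigma2 / (2.0 * alpha) * np.exp(-2.0 * alpha * (T - s)) * (-np.expm1(-2.0 * alpha * s))


def eb_covariance(tree: Phylogeny, sigma2: float, r: float) -> np.ndarray:
    """Early-burst tip covariance; the r -> 0 limit is the BM covariance."""
    s = tree.shared_path_matrix()
    if abs(r) < 1e-12:
        return sigma2 * s
    return sigma2 * np.expm1(r * s) / r


def mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate-normal log density via Cholesky."""
    x = np.asarray(x, float)
    d = x - np.asarray(mean, float)
    cf = cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ss = float(d @ cho_solve(cf, d))
    return -0.5 * (len(x) * _LOG2PI + logdet + ss)
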