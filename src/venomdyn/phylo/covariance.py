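"""Multivariate phylogenetic covariance and phylomorphospace PCA.

Under multivariate BM the tip matrix X (n species x p families, on the
log(TPM+1) scale upstream) is matrix normal with row covariance C (the
tree) and column covariance R, the evolutionary trait covariance. The ML
root mean and the (n-1)-divisor estimator are

    a_hat = (1' C^-1 1)^-1 1' C^-1 X
    R_hat = (X - 1 a_hat)' C^-1 (X - 1 a_hat) / (n - 1)

Entry-wise 95% confidence bounds come from a parametric bootstrap:
simulate B datasets under the fitted matrix-normal model, refit, take
percentiles; an off-diagonal covariance is significant when its interval
excludes zero.

The phylomorphospace is the eigenbasis of R_hat: tip scores are the
centered traits projected on the eigenvectors, ancestral node scores are
the BM ancestral reconstructions projected into the same plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from venomdyn.core_io import Phylogeny
from venomdyn.phylo.asr import asr_bm

__all__ = ["PhyloCovarianceResult", "phylo_covariance", "phylomorphospace_pca", "Phylomorphospace"]


@dataclass
class PhyloCovarianceResult:
    """Evolutionary covariance estimate with bootstrap 95% intervals."""

    covariance: pd.DataFrame  # R_hat, p x p
    root_mean: pd.Series  # a_hat, length p
    lower: pd.DataFrame
    upper: pd.DataFrame
    significant: pd.DataFrame  # off-diagonal flags; diagonal False
    n_bootstrap: int


def _fit_mbm(X: np.ndarray, cf) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    one = np.ones(n)
    ci1 = cho_solve(cf, one)
    a = (ci1 @ X) / (ci1 @ one)
    D = X - a
    R = D.T @ cho_solve(cf, D) / (n - 1)
    return a, R


def phylo_covariance(
    traits: pd.DataFrame,
    tree: Phylogeny,
    n_bootstrap: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> PhyloCovarianceResult:
    """ML multivariate-BM covariance with parametric-bootstrap intervals.

    ``traits`` is species x family with index equal to the tip labels;
    at least p + 2 species are required for p families.
    """
    if set(traits.index) != set(tree.tip_labels):
        raise ValueError("trait index must equal the tree tip set")
    X = traits.loc[tree.tip_labels].to_numpy(float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2 = {p + 2} species for {p} families")
    if np.linalg.matrix_rank(X - X.mean(0)) < min(n - 1, p):
        warnings.warn("rank-deficient trait matrix; covariance is singular")
    C = tree.shared_path_matrix()
    cf = cho_factor(C, lower=True)
    a, R = _fit_mbm(X, cf)

    # factor R for sampling, tolerating PSD rank deficiency via eigh
    evals, evecs = np.linalg.eigh(R)
    F = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    Lc = cholesky(C, lower=True)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, p, p))
    for b in range(n_bootstrap):
        Z = rng.standard_normal((n, p))
        Xb = a + Lc @ Z @ F.T
        _, Rb = _fit_mbm(Xb, cf)
        boots[b] = Rb
    q = (1.0 - level) / 2.0
    lower = np.quantile(boots, q, axis=0)
    upper = np.quantile(boots, 1.0 - q, axis=0)
    signif = (lower > 0) | (upper < 0)
    np.fill_diagonal(signif, False)

    fams = list(traits.columns)
    return PhyloCovarianceResult(
        covariance=pd.DataFrame(R, index=fams, columns=fams),
        root_mean=pd.Series(a, index=fams),
        lower=pd.DataFrame(lower, index=fams, columns=fams),
        upper=pd.DataFrame(upper, index=fams, columns=fams),
        significant=pd.DataFrame(signif, index=fams, columns=fams),
        n_bootstrap=n_bootstrap,
    )


@dataclass
class Phylomorphospace:
    """PCA of the evolutionary covariance with tips and ancestors projected."""

    tip_scores: pd.DataFrame  # species x component
    node_scores: pd.DataFrame  # internal node id x component
    loadings: pd.DataFrame  # family x component (orthonormal columns)
    variance_fractions: pd.Series


def phylomorphospace_pca(
    result: PhyloCovarianceResult, traits: pd.DataFrame, tree: Phylogeny
) -> Phylomorphospace:
    """Project tips and BM ancestral states onto the eigenbasis of R_hat."""
    fams = list(result.covariance.columns)
    X = traits.loc[tree.tip_labels, fams].to_numpy(float)
    a = result.root_mean.to_numpy()
    evals, evecs = np.linalg.eigh(result.covariance.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, V = evals[order], evecs[:, order]
    frac = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    comp = [f"PC{i + 1}" for i in range(len(fams))]
    tip_scores = (X - a) @ V
    node_states = []
    node_index = None
    for j in range(len(fams)):
        states = asr_bm(X[:, j], tree)
        node_states.append(states.estimates.to_numpy())
        node_index = states.estimates.index
    node_scores = (np.column_stack(node_states) - a) @ V
    return Phylomorphospace(
        tip_scores=pd.DataFrame(tip_scores, index=tree.tip_labels, columns=comp),
        node_scores=pd.DataFrame(node_scores, index=node_index, columns=comp),
        loadings=pd.DataFrame(V, index=fams, columns=comp),
        variance_fractions=pd.Series(frac, index=comp),
    )
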