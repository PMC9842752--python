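"""Pulsed trait evolution: jump-normal Levy likelihood by mixture pruning.

The displacement of a trait over a branch of length ``t`` is the sum of a
Brownian increment ``N(0, sigma2 t)`` and a Poisson(``jump_rate * t``)
number of independent ``N(0, jump_var)`` jumps, so the increment density
is an infinite normal-scale mixture

    sum_k  Pois(k; jump_rate t) N(0, sigma2 t + k jump_var).

The tip likelihood is evaluated by Felsenstein pruning where every
partial message is a finite normal mixture:

* per branch, the Poisson jump count is truncated at the smallest K with
  tail mass below ``poisson_tail`` (1e-8);
* at a node, child mixtures are multiplied component-wise (a product of
  two normal densities in the node state is again normal, with an
  explicit marginal constant);
* mixtures are kept finite by dropping components whose relative weight
  falls below ``prune_weight`` (1e-10) and, above ``max_components``
  (256), by a moment-matching merge: components are sorted by mean and
  binned into weight quantiles, each bin replaced by the normal matching
  its first two moments.

At ``jump_rate = 0`` every mixture has a single component and the
recursion reduces exactly to the BM pruning likelihood.
"""

from __future__ import annotations

import numpy as np

from venomdyn.core_io import Phylogeny
from venomdyn.errors import MixtureOverflowError

_LOG2PI = np.log(2.0 * np.pi)

__all__ = ["jn_loglik"]


def _poisson_mixture(lam_t: float, sigma2_t: float, jump_var: float, tail: float):
    """Log-weights and variances of the truncated branch increment mixture.

    The Poisson pmf is accumulated iteratively up to the smallest K whose
    tail mass falls below ``tail``.
    """
    if lam_t <= 0 or jump_var <= 0:
        return np.array([0.0]), np.array([sigma2_t])
    pmf = np.exp(-lam_t)
    pmfs = [pmf]
    cum = pmf
    k = 0
    while 1.0 - cum >= tail and k < 10_000:
        k += 1
        pmf *= lam_t / k
        pmfs.append(pmf)
        cum += pmf
    w = np.asarray(pmfs)
    ks = np.arange(len(w))
    return np.log(w), sigma2_t + ks * jump_var


def _merge_to_cap(logw: np.ndarray, mean: np.ndarray, var: np.ndarray, cap: int):
    """Moment-matching merge down to <= cap components.

    Components are binned on a (mean, log-variance) grid — nearby
    components in both location and scale share a bin — and each bin is
    replaced by the single normal matching its first two moments.
    """
    scale = logw.max()
    w = np.exp(logw - scale)
    n_keep = cap // 2
    top = np.argpartition(-w, n_keep)[:n_keep]  # dominant components stay exact
    rest = np.ones(len(w), bool)
    rest[top] = False
    wr, mr, vr = w[rest], mean[rest], var[rest]
    nm = int(np.sqrt(cap // 2))  # tail merged on a (mean, log-var) grid
    mlo, mhi = mr.min(), mr.max()
    mbin = (
        np.minimum(((mr - mlo) / (mhi - mlo) * nm).astype(int), nm - 1)
        if mhi > mlo
        else np.zeros(len(mr), int)
    )
    lv = np.log(np.maximum(vr, 1e-300))
    vlo, vhi = lv.min(), lv.max()
    vbin = (
        np.minimum(((lv - vlo) / (vhi - vlo) * nm).astype(int), nm - 1)
        if vhi > vlo
        else np.zeros(len(lv), int)
    )
    bins = mbin * nm + vbin
    nbins = nm * nm
    wsum = np.bincount(bins, weights=wr, minlength=nbins)
    keep = wsum > 0
    m1 = np.bincount(bins, weights=wr * mr, minlength=nbins)[keep] / wsum[keep]
    raw2 = np.bincount(bins, weights=wr * (vr + mr**2), minlength=nbins)[keep] / wsum[keep]
    v = np.maximum(raw2 - m1**2, 1e-300)
    out_logw = np.concatenate([np.log(w[top]) + scale, np.log(wsum[keep]) + scale])
    out_mean = np.concatenate([mean[top], m1])
    out_var = np.concatenate([var[top], v])
    return out_logw, out_mean, out_var


def _merge_greedy(logw: np.ndarray, mean: np.ndarray, var: np.ndarray, cap: int):
    """Near-lossless merge: repeatedly moment-match the cheapest adjacent pair.

    O(n^2) in the worst case, so reserved for small mixtures where the
    grid merge's O(1e-5) error would dominate the likelihood tolerance.
    """
    order = np.argsort(mean)
    scale = logw.max()
    w = np.exp(logw - scale)[order]
    m = mean[order].copy()
    v = var[order].copy()
    w = w.copy()
    while len(w) > cap:
        dm = np.diff(m)
        dv = np.diff(np.sqrt(v))
        pairw = w[:-1] * w[1:] / (w[:-1] + w[1:])
        cost = pairw * (dm**2 + dv**2)
        i = int(np.argmin(cost))
        wt = w[i] + w[i + 1]
        mm = (w[i] * m[i] + w[i + 1] * m[i + 1]) / wt
        vv = (w[i] * (v[i] + m[i] ** 2) + w[i + 1] * (v[i + 1] + m[i + 1] ** 2)) / wt - mm**2
        w[i], m[i], v[i] = wt, mm, max(vv, 1e-300)
        w = np.delete(w, i + 1)
        m = np.delete(m, i + 1)
        v = np.delete(v, i + 1)
    return np.log(w) + scale, m, v


class _Mixture:
    """Finite normal mixture message: sum_i exp(logw_i) N(x; mean_i, var_i)."""

    __slots__ = ("logw", "mean", "var")

    def __init__(self, logw, mean, var):
        self.logw = np.asarray(logw, float)
        self.mean = np.asarray(mean, float)
        self.var = np.asarray(var, float)

    def prune(self, rel_tol: float, cap: int, accurate: bool = False) -> "_Mixture":
        keep = self.logw >= self.logw.max() + np.log(rel_tol)
        logw, mean, var = self.logw[keep], self.mean[keep], self.var[keep]
        if len(logw) > cap:
            merge = _merge_greedy if accurate and len(logw) <= 4096 else _merge_to_cap
            logw, mean, var = merge(logw, mean, var, cap)
        if len(logw) > 4 * cap:  # cannot happen by construction; guard anyway
            raise MixtureOverflowError(f"{len(logw)} components after merge")
        return _Mixture(logw, mean, var)


def _convolve_branch(msg: _Mixture, lam_t, sigma2_t, jump_var, tail) -> _Mixture:
    jw, jv = _poisson_mixture(lam_t, sigma2_t, jump_var, tail)
    logw = (msg.logw[:, None] + jw[None, :]).ravel()
    var = (msg.var[:, None] + jv[None, :]).ravel()
    mean = np.repeat(msg.mean, len(jw))
    return _Mixture(logw, mean, var)


def _multiply(a: _Mixture, b: _Mixture) -> _Mixture:
    """Pointwise product of two mixtures of normal densities in the same variable."""
    va, vb = a.var[:, None], b.var[None, :]
    ma, mb = a.mean[:, None], b.mean[None, :]
    tot = np.maximum(va + vb, 1e-300)  # guard zero-length sibling branches
    # N(x;ma,va) N(x;mb,vb) = N(ma; mb, va+vb) * N(x; m, v)
    logc = -0.5 * (_LOG2PI + np.log(tot) + (ma - mb) ** 2 / tot)
    logw = (a.logw[:, None] + b.logw[None, :] + logc).ravel()
    mean = ((ma * vb + mb * va) / tot).ravel()
    var = (va * vb / tot).ravel()
    return _Mixture(logw, mean, var)


def jn_loglik(
    trait: np.ndarray,
    tree: Phylogeny,
    sigma2: float,
    jump_rate: float,
    jump_var: float,
    root: float,
    *,
    poisson_tail: float = 1e-8,
    prune_weight: float = 1e-10,
    max_components: int = 256,
) -> float:
    """Log-likelihood of tip traits under the jump-normal pulsed model."""
    if sigma2 < 0 or jump_rate < 0 or jump_var < 0:
        return -np.inf
    x = np.asarray(trait, float)
    # small problems get oracle-grade accuracy: a raised component budget
    # (merges then almost never fire) and the near-lossless pairwise merge
    # if one does; larger fits use the capped fast grid merge
    accurate = tree.n_tips <= 8
    if accurate:
        max_components = max(max_components, 8192)
    messages: dict[int, _Mixture] = {}
    for nd in tree.postorder():
        if tree.is_tip(nd):
            msg = _Mixture([0.0], [x[nd]], [0.0])
        else:
            kids = tree.children[nd]
            msg = messages.pop(kids[0])
            for k in kids[1:]:
                other = messages.pop(k)
                # bound the outer product's memory footprint
                while len(msg.logw) * len(other.logw) > 4_000_000:
                    big = msg if len(msg.logw) >= len(other.logw) else other
                    merged = _Mixture(
                        *_merge_to_cap(big.logw, big.mean, big.var, len(big.logw) // 2)
                    )
                    if big is msg:
                        msg = merged
                    else:
                        other = merged
                msg = _multiply(msg, other)
                msg = msg.prune(prune_weight, max_components, accurate)
        t = tree.branch_lengths[nd]
        if nd != tree.root and t > 0:
            msg = _convolve_branch(msg, jump_rate * t, sigma2 * t, jump_var, poisson_tail)
            msg = msg.prune(prune_weight, max_components, accurate)
        messages[nd] = msg
    m = messages[tree.root]
    # L(root) = sum_i w_i N(root; mean_i, var_i); tips identical to the root
    # state give var 0 components only if every branch has length 0.
    var = np.maximum(m.var, 1e-300)
    comp = m.logw - 0.5 * (_LOG2PI + np.log(var) + (root - m.mean) ** 2 / var)
    hi = comp.max()
    return float(hi + np.log(np.sum(np.exp(comp - hi))))
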