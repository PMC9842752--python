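"""ML ancestral state reconstruction under Brownian motion.

Two-pass Gaussian message passing on the tree: the upward pass collects,
for every node, the precision-weighted summary of the tip data below it;
the downward pass combines each node's upward summary with the message
arriving from the rest of the tree. For a Gaussian model the resulting
conditional means are exactly the joint-ML / GLS ancestral estimates, and
the conditional variances scale with the Brownian rate.

``asr_composition`` applies the scalar reconstruction to each
toxin-family fraction independently, then clips node compositions to
[0, 1] and renormalizes them to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from venomdyn.core_io import Phylogeny
from venomdyn.phylo.fit import fit_bm

__all__ = ["AncestralStates", "asr_bm", "asr_composition"]


@dataclass
class AncestralStates:
    """Per-internal-node ML state estimates and variances (node id indexed)."""

    estimates: pd.Series
    variances: pd.Series

    @property
    def root_estimate(self) -> float:
        return float(self.estimates.iloc[-1])


def _combine(means, variances):
    """Precision-weighted combination of Gaussian messages (var=inf allowed)."""
    prec = np.array([0.0 if np.isinf(v) else 1.0 / v for v in variances])
    if prec.sum() == 0:
        return 0.0, np.inf
    m = float(np.dot(prec, means) / prec.sum())
    return m, 1.0 / prec.sum()


def asr_bm(trait: np.ndarray, tree: Phylogeny, sigma2: float | None = None) -> AncestralStates:
    """ML ancestral states under BM via two-pass pruning.

    When ``sigma2`` is omitted the ML Brownian rate is estimated from the
    tips; reported variances are conditional variances times that rate.
    """
    x = np.asarray(trait, float)
    if tree.n_tips < 2:
        raise ValueError("ASR needs at least 2 tips")
    if sigma2 is None:
        if tree.n_tips >= 3:
            fit = fit_bm(x, tree)
            sigma2 = fit.params.sigma2 if not fit.degenerate else 0.0
        else:
            sigma2 = np.nan

    n = tree.n_nodes
    up_mean = np.zeros(n)
    up_var = np.zeros(n)  # variance of the upward message about the node state
    for nd in tree.postorder():
        if tree.is_tip(nd):
            up_mean[nd], up_var[nd] = x[nd], 0.0
        else:
            kids = tree.children[nd]
            if any(
                not tree.is_tip(k) and tree.branch_lengths[k] == 0 for k in kids
            ):
                warnings.warn(
                    "zero-length internal branch: child state tied to parent"
                )
            ms = [up_mean[k] for k in kids]
            vs = [up_var[k] + tree.branch_lengths[k] for k in kids]
            up_mean[nd], up_var[nd] = _combine(ms, vs)

    down_mean = np.zeros(n)
    down_var = np.full(n, np.inf)  # message from the rest of the tree
    est = np.zeros(n)
    var = np.zeros(n)
    for nd in tree.preorder():
        if nd == tree.root:
            est[nd], var[nd] = up_mean[nd], up_var[nd]
        else:
            p = int(tree.parent[nd])
            sib_ms = [down_mean[p]]
            sib_vs = [down_var[p]]
            for s in tree.children[p]:
                if s != nd:
                    sib_ms.append(up_mean[s])
                    sib_vs.append(up_var[s] + tree.branch_lengths[s])
            m, v = _combine(sib_ms, sib_vs)
            down_mean[nd], down_var[nd] = m, v + tree.branch_lengths[nd]
            if not tree.is_tip(nd):
                est[nd], var[nd] = _combine(
                    [up_mean[nd], down_mean[nd]], [up_var[nd], down_var[nd]]
                )

    # stable order: internal node ids ascending, root moved last
    internal = sorted(nd for nd in range(n) if not tree.is_tip(nd))
    order = [nd for nd in internal if nd != tree.root] + [tree.root]
    return AncestralStates(
        estimates=pd.Series([est[nd] for nd in order], index=order),
        variances=pd.Series([var[nd] * sigma2 for nd in order], index=order),
    )


def asr_composition(
    compositions: pd.DataFrame, tree: Phylogeny, sigma2: float | None = None
) -> pd.DataFrame:
    """Reconstruct ancestral toxin-family compositions per internal node.

    ``compositions`` is species x family fractions with the index equal
    to the tree's tip labels. Each family fraction is reconstructed
    independently under BM; node vectors are clipped to [0, 1] and
    renormalized to sum to one.
    """
    if set(compositions.index) != set(tree.tip_labels):
        raise ValueError("composition index must equal the tree tip set")
    X = compositions.loc[tree.tip_labels]
    per_family = {}
    for fam in X.columns:
        states = asr_bm(X[fam].to_numpy(), tree, sigma2=sigma2)
        per_family[fam] = states.estimates
    node_df = pd.DataFrame(per_family)
    clipped = node_df.clip(lower=0.0, upper=1.0)
    sums = clipped.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        warnings.warn("all-zero node composition after clipping; using uniform")
        clipped.loc[zero, :] = 1.0 / clipped.shape[1]
        sums = clipped.sum(axis=1)
    return clipped.div(sums, axis=0)
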