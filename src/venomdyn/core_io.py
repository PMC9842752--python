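"""Domain types and readers: phylogenies, sequences, expression tables.

The :class:`Phylogeny` container is the hub of the comparative half of the
package: it provides the tree height ``T``, the shared-path matrix
``s_ij`` (root-to-MRCA path length for each tip pair) and the Brownian
covariance matrix ``C`` (``C_ij = s_ij``, ``C_ii`` = root-to-tip distance)
that every trait-evolution model is parameterized on.

Newick parsing and writing are delegated to dendropy; this module adds the
validation the pipeline requires (unique tips, branch lengths everywhere)
and the array-based representation the likelihood code consumes.
"""

from __future__ import annotations

import io
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from venomdyn.errors import FastaFormatError, NewickParseError

__all__ = [
    "Phylogeny",
    "read_newick",
    "read_fasta",
    "compute_phylo_covariance_matrix",
    "read_expression_tsv",
    "read_annotation_tsv",
]


class Phylogeny:
    """A rooted tree with branch lengths, stored as parent/child arrays.

    Node ids are integers ``0..n_nodes-1``; tips come first in
    first-encountered (Newick) order, then internal nodes in postorder.
    The root has parent ``-1`` and branch length 0.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_lengths: Sequence[float],
        tip_labels: Sequence[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self._validate()
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self._depths: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        if len(self.parent) != len(self.branch_lengths):
            raise ValueError("parent and branch_lengths length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be nonnegative")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted(
                {t for t in self.tip_labels if self.tip_labels.count(t) > 1}
            )
            raise NewickParseError(f"duplicate tip labels: {dupes}")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        """Convert a dendropy tree; every non-root edge must carry a length."""
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        index.update({id(nd): len(leaves) + i for i, nd in enumerate(internals)})
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n, dtype=float)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    label = nd.taxon.label if nd.taxon else "(internal node)"
                    raise NewickParseError(f"missing branch length on edge to {label!r}")
                blen[i] = float(nd.edge.length)
        labels = []
        for nd in leaves:
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("unlabeled tip in tree")
            labels.append(nd.taxon.label)
        return cls(parent, blen, labels)

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_tip(self, i: int) -> bool:
        return i < self.n_tips

    def postorder(self) -> Iterator[int]:
        """Node ids, children before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return iter(reversed(order))

    def preorder(self) -> Iterator[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(reversed(self.children[nd]))
        return iter(order)

    # -- derived quantities ------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        if self._depths is None:
            depths = np.zeros(self.n_nodes)
            for nd in self.preorder():
                p = self.parent[nd]
                if p >= 0:
                    depths[nd] = depths[p] + self.branch_lengths[nd]
            self._depths = depths
        return self._depths

    @property
    def height(self) -> float:
        """Tree height T: the maximum root-to-tip path length."""
        return float(self.node_depths()[: self.n_tips].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = self.node_depths()[: self.n_tips]
        h = depths.max()
        if h == 0:
            return True
        return bool(np.all(np.abs(depths - h) <= rtol * h))

    def shared_path_matrix(self) -> np.ndarray:
        """s_ij = root-to-MRCA path length for tips i, j; s_ii = tip depth.

        This equals the Brownian covariance matrix C up to the rate
        parameter. Computed by sweeping internal nodes in postorder and
        assigning the node depth to every tip pair split between two of
        its child subtrees: O(n^2) overall.
        """
        n = self.n_tips
        depths = self.node_depths()
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for nd in self.postorder():
            if self.is_tip(nd):
                tipsets[nd] = np.array([nd], dtype=int)
                continue
            kids = self.children[nd]
            sets = [tipsets.pop(k) for k in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    C[np.ix_(sets[a], sets[b])] = depths[nd]
                    C[np.ix_(sets[b], sets[a])] = depths[nd]
            tipsets[nd] = np.concatenate(sets)
        np.fill_diagonal(C, depths[:n])
        return C

    def mrca_depth(self, node: int, tip: int) -> float:
        """Root-to-MRCA path length between an arbitrary node and a tip."""
        anc_a = set()
        i = node
        while i >= 0:
            anc_a.add(i)
            i = int(self.parent[i])
        i = tip
        while i not in anc_a:
            i = int(self.parent[i])
        return float(self.node_depths()[i])

    # -- I/O ---------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def render(nd: int) -> str:
            if self.is_tip(nd):
                core = self.tip_labels[nd]
            else:
                core = "(" + ",".join(render(k) for k in self.children[nd]) + ")"
            if nd == self.root:
                return core
            return f"{core}:{self.branch_lengths[nd]:.{precision}g}"

        return render(self.root) + ";"

    def scaled_to_height(self, height: float = 1.0) -> "Phylogeny":
        """Return a copy with all branch lengths scaled so the tree height equals ``height``."""
        h = self.height
        if h <= 0:
            raise ValueError("cannot scale a zero-height tree")
        return Phylogeny(
            self.parent, self.branch_lengths * (height / h), self.tip_labels
        )

    def make_ultrametric_mean_path(self) -> "Phylogeny":
        """Force ultrametricity by adjusting terminal branches to the mean tip depth.

        A convenience only; this is NOT equivalent to penalized-likelihood
        dating (chronos) and must not be used as a substitute for a
        time-calibrated tree.
        """
        depths = self.node_depths()[: self.n_tips]
        target = depths.mean()
        blen = self.branch_lengths.copy()
        for tip in range(self.n_tips):
            adj = blen[tip] + (target - depths[tip])
            if adj < 0:
                raise ValueError(
                    f"tip {self.tip_labels[tip]!r} cannot reach mean depth "
                    "without a negative terminal branch"
                )
            blen[tip] = adj
        return Phylogeny(self.parent, blen, self.tip_labels)


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths into a Phylogeny.

    Raises
    ------
    NewickParseError
        On unbalanced parentheses, duplicate tip labels, or a missing
        branch length, naming the offending token where possible.
    """
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


def compute_phylo_covariance_matrix(tree: Phylogeny) -> np.ndarray:
    """Brownian covariance matrix C over tips (C_ij = shared path, C_ii = depth)."""
    return tree.shared_path_matrix()


# IUPAC nucleotide codes and amino-acid codes (incl. extended B/Z/X/J/U/O)
# jointly cover A-Z; gap and stop are permitted.
_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ*-")


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into ordered ``(identifier, SEQUENCE)`` pairs.

    Sequences are upper-cased; an empty record or a character outside the
    IUPAC nucleotide/amino-acid alphabets raises FastaFormatError naming
    the record.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"empty record {rec.id!r}")
        bad = set(seq) - _ALLOWED
        if bad:
            raise FastaFormatError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id!r}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in records)


def read_expression_tsv(path_or_buf) -> pd.DataFrame:
    """Read a sample x transcript TPM table (first column = sample id)."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("negative TPM values in expression table")
    return df


def read_annotation_tsv(path_or_buf) -> pd.Series:
    """Read a transcript -> toxin-family map (columns: transcript, family)."""
    df = pd.read_csv(path_or_buf, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("annotation table needs transcript and family columns")
    transcripts = df.iloc[:, 0]
    if transcripts.duplicated().any():
        dupes = transcripts[transcripts.duplicated()].tolist()
        raise ValueError(f"transcripts annotated to multiple families: {dupes}")
    return pd.Series(df.iloc[:, 1].values, index=transcripts.values, name="family")
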