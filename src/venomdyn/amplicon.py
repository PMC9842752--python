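"""Amplicon haplotyping of a clustered toxin gene family.

Joined amplicons are size- and ambiguity-filtered (300-500 bp, ACGT
only), primer-trimmed, and each sample is randomly subsampled to a fixed
depth (14,800 reads) so read counts are comparable; shallower samples are
excluded. A sequence is called a biological variant (rather than a
PCR/sequencing artifact) when it reaches 100 reads in at least one
individual and occurs in more than one individual. Samples are clustered
by 1 - Spearman rank correlation of their variant-abundance profiles,
and "core" haplotypes — variant sets travelling together on one
chromosome — are deduced by exact search anchored on homozygous
individuals, whose whole variant set is a single haplotype.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.stats import spearmanr

__all__ = [
    "GenotypeProfile",
    "CoreHaplotype",
    "filter_amplicons",
    "trim_primers",
    "subsample_reads",
    "call_variants",
    "cluster_samples",
    "infer_core_haplotypes",
]


@dataclass
class GenotypeProfile:
    """Per-individual variant read counts (post subsampling) and abundances."""

    individual: str
    population: str
    counts: pd.Series  # variant -> read count

    @property
    def abundances(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts * 0.0

    def presence_set(self, threshold: int) -> frozenset[str]:
        return frozenset(self.counts.index[self.counts >= threshold])


@dataclass
class CoreHaplotype:
    """One chromosomal allele of the locus: the set of variants it carries."""

    name: str
    variants: frozenset[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a core haplotype cannot be empty")


def filter_amplicons(
    seqs: list[tuple[str, str]], min_len: int = 300, max_len: int = 500
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Keep amplicons within the inclusive size window and free of ambiguity.

    Returns (retained records, rejection tally with keys 'too_short',
    'too_long', 'ambiguous'). The tallies partition the rejected input.
    """
    kept = []
    tally = {"too_short": 0, "too_long": 0, "ambiguous": 0}
    for name, seq in seqs:
        if len(seq) < min_len:
            tally["too_short"] += 1
        elif len(seq) > max_len:
            tally["too_long"] += 1
        elif set(seq) - set("ACGT"):
            tally["ambiguous"] += 1
        else:
            kept.append((name, seq))
    return kept, tally


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(
    seq: str, fwd_primer: str, rev_primer: str, max_mismatch: int = 1
) -> tuple[str | None, str]:
    """Strip the forward primer at the 5' end and the reverse complement of
    the reverse primer at the 3' end, each tolerating ``max_mismatch``
    substitutions. Returns (trimmed or None, reason)."""
    seq = seq.upper()
    f, r = fwd_primer.upper(), _revcomp(rev_primer.upper())
    if len(f) + len(r) >= len(seq):
        return None, "sequence shorter than primers"
    if _mismatches(seq[: len(f)], f) > max_mismatch:
        return None, "forward primer not found"
    if _mismatches(seq[-len(r):], r) > max_mismatch:
        return None, "reverse primer not found"
    return seq[len(f) : len(seq) - len(r)], "ok"


def subsample_reads(
    seqs: list[str], depth: int = 14_800, seed: int = 0
) -> list[str] | None:
    """Uniform subsample without replacement to exactly ``depth`` reads.

    Returns None when the sample is too shallow — such samples are
    excluded from downstream analysis.
    """
    if len(seqs) < depth:
        return None
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seqs), size=depth, replace=False)
    return [seqs[i] for i in idx]


def call_variants(
    counts: pd.DataFrame,
    min_abundance: int = 100,
    min_individuals: int = 2,
    strict: bool = False,
) -> list[str]:
    """Distinguish biological variants from artifacts.

    ``counts`` is individual x sequence. A sequence is a variant iff it
    reaches ``min_abundance`` reads in at least one individual AND occurs
    (count >= 1) in at least ``min_individuals`` individuals. With
    ``strict=True`` the alternative reading is applied: the abundance bar
    must be met in ``min_individuals`` individuals.
    """
    hit = counts >= min_abundance
    present = counts >= 1
    if strict:
        ok = hit.sum(axis=0) >= min_individuals
    else:
        ok = (hit.any(axis=0)) & (present.sum(axis=0) >= min_individuals)
    return [str(c) for c in counts.columns[ok]]


def cluster_samples(
    profiles: list[GenotypeProfile],
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Hierarchical clustering of samples by Spearman distance.

    Distance is 1 - Spearman rho of the variant relative-abundance
    vectors; agglomeration is complete linkage; ties are made
    deterministic by pre-sorting samples by identifier. Returns (linkage
    matrix, leaf-ordered sample names, condensed distance matrix as a
    square array).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    profiles = sorted(profiles, key=lambda p: p.individual)
    names = [p.individual for p in profiles]
    A = pd.concat([p.abundances for p in profiles], axis=1).fillna(0.0).T
    if A.shape[1] < 2:
        raise ValueError("need at least 2 variants to cluster")
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = A.iloc[i].to_numpy(), A.iloc[j].to_numpy()
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn("constant abundance vector: Spearman undefined, distance 1")
                d = 1.0
            else:
                rho = spearmanr(xi, xj).statistic
                d = 1.0 - rho
            D[i, j] = D[j, i] = d
    condensed = D[np.triu_indices(n, 1)]
    Z = linkage(condensed, method="complete")
    order = [names[i] for i in leaves_list(Z)]
    return Z, order, D


@dataclass
class HaplotypeInference:
    cores: list[CoreHaplotype]
    assignments: dict[str, tuple[str, str] | None]  # individual -> (hap, hap) or None
    unexplained: list[str] = field(default_factory=list)


def _explains(obs: frozenset, cores: list[frozenset]) -> tuple[int, int] | None:
    """First pair of core indices (i <= j) whose union equals the observed set."""
    for i, j in itertools.combinations_with_replacement(range(len(cores)), 2):
        if cores[i] | cores[j] == obs:
            return i, j
    return None


def infer_core_haplotypes(
    profiles: list[GenotypeProfile],
    presence_threshold: int = 100,
    max_cores: int = 8,
) -> HaplotypeInference:
    """Deduce core haplotypes by exact search over observed presence-sets.

    Candidates are the distinct observed per-individual presence-sets
    (a homozygote's whole set is itself one haplotype). The result is the
    minimum-cardinality candidate subset H such that every individual's
    set is the union of one or two members of H; ties prefer (i) more
    individuals explained as homozygotes (whole set in H), then (ii) the
    lexicographically smallest sorted set contents.
    """
    obs_sets: dict[str, frozenset] = {}
    for p in profiles:
        s = p.presence_set(presence_threshold)
        if s:
            obs_sets[p.individual] = s
    distinct = sorted(set(obs_sets.values()), key=lambda s: sorted(s))
    best: tuple | None = None
    for size in range(1, min(max_cores, len(distinct)) + 1):
        for combo in itertools.combinations(distinct, size):
            cores = list(combo)
            pairings = {}
            ok = True
            for ind, s in obs_sets.items():
                pair = _explains(s, cores)
                if pair is None:
                    ok = False
                    break
                pairings[ind] = pair
            if not ok:
                continue
            homozygotes = sum(
                1 for ind, s in obs_sets.items() if s in combo
            )
            key = (-homozygotes, tuple(sorted(tuple(sorted(c)) for c in combo)))
            if best is None or key < best[0]:
                best = (key, cores, pairings)
        if best is not None:
            break
    if best is None:
        # no covering subset within the size cap: report every individual
        return HaplotypeInference(
            cores=[], assignments={i: None for i in obs_sets}, unexplained=sorted(obs_sets)
        )
    _, cores, pairings = best
    named = [
        CoreHaplotype(f"H{i + 1}", c)
        for i, c in enumerate(sorted(cores, key=lambda s: (-len(s), sorted(s))))
    ]
    lookup = {c.variants: c.name for c in named}
    assignments = {}
    for ind, (i, j) in pairings.items():
        assignments[ind] = (lookup[cores[i]], lookup[cores[j]])
    for p in profiles:
        if p.individual not in assignments:
            assignments[p.individual] = None
    return HaplotypeInference(cores=named, assignments=assignments)
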