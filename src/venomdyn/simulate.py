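"""Synthetic data with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: ultrametric
pure-birth trees; tip traits evolved under BM/OU/EB/JN (by recursive
simulation along branches — a code path independent of the pruning
likelihoods, so recovery tests are not circular); diploid populations
drawn in Hardy-Weinberg proportions from a pool of locus haplotypes;
amplicon read sets with per-base substitution artifacts; triplicate
multiplex qPCR plates with a single-copy control gene and a calibrator
of known copy number; and paired reads sampled from a cluster of
near-identical gene copies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from venomdyn.core_io import Phylogeny
from venomdyn.locus import HaplotypeArray
from venomdyn.phylo.fit import ModelParams

__all__ = [
    "simulate_tree",
    "simulate_traits",
    "simulate_locus_population",
    "simulate_amplicon_reads",
    "simulate_qpcr_plate",
    "simulate_cluster_readpairs",
]

_BASES = np.array(list("ACGT"))


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, scaled to height 1."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    phylo = Phylogeny.from_dendropy(tree)
    # the process stops at the nth birth, leaving that cherry with
    # zero-length branches; run the Exp(n * birth_rate) waiting time to the
    # (unrealized) next birth so every pending lineage gains positive length
    extra = rng.expovariate(n_tips * birth_rate)
    blen = phylo.branch_lengths.copy()
    blen[: phylo.n_tips] += extra
    phylo = Phylogeny(phylo.parent, blen, phylo.tip_labels)
    return phylo.scaled_to_height(1.0)


def _branch_increment(
    rng: np.random.Generator,
    x0: float,
    t0: float,
    t1: float,
    params: ModelParams,
) -> float:
    """Simulate the trait at the end of a branch running from time t0 to t1."""
    dt = t1 - t0
    if dt <= 0:
        return x0
    m = params.model
    if m == "BM":
        return x0 + rng.normal(0.0, np.sqrt(params.sigma2 * dt))
    if m == "OU":
        decay = np.exp(-params.alpha * dt)
        var = params.sigma2 / (2 * params.alpha) * (1 - np.exp(-2 * params.alpha * dt))
        return params.theta + (x0 - params.theta) * decay + rng.normal(0.0, np.sqrt(var))
    if m == "EB":
        # rate sigma2 * exp(r t): integrated variance over [t0, t1]
        r = params.r
        if abs(r) < 1e-12:
            var = params.sigma2 * dt
        else:
            var = params.sigma2 * (np.exp(r * t1) - np.exp(r * t0)) / r
        return x0 + rng.normal(0.0, np.sqrt(var))
    if m == "JN":
        x = x0 + rng.normal(0.0, np.sqrt(params.sigma2 * dt)) if params.sigma2 > 0 else x0
        n_jumps = rng.poisson(params.jump_rate * dt)
        if n_jumps > 0:
            x += rng.normal(0.0, np.sqrt(params.jump_var), size=n_jumps).sum()
        return x
    raise ValueError(f"unknown model {m!r}")


def simulate_traits(
    tree: Phylogeny,
    params: ModelParams,
    seed: int = 0,
    trait_covariance: np.ndarray | None = None,
) -> np.ndarray:
    """Tip traits simulated recursively along branches.

    Returns a vector over tips (tree tip order), or an n x p matrix when
    ``trait_covariance`` R is given (multivariate BM with evolutionary
    covariance R; ``params`` must then be BM with sigma2 = 1).
    """
    rng = np.random.default_rng(seed)
    depths = tree.node_depths()
    if trait_covariance is not None:
        R = np.asarray(trait_covariance, float)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
        p = len(R)
        states = {tree.root: np.full(p, params.root, float)}
        for nd in tree.preorder():
            if nd == tree.root:
                continue
            par = int(tree.parent[nd])
            dt = tree.branch_lengths[nd]
            states[nd] = states[par] + L @ rng.standard_normal(p) * np.sqrt(dt)
        return np.vstack([states[i] for i in range(tree.n_tips)])
    states_s = {tree.root: float(params.root)}
    for nd in tree.preorder():
        if nd == tree.root:
            continue
        par = int(tree.parent[nd])
        states_s[nd] = _branch_increment(
            rng, states_s[par], depths[par], depths[nd], params
        )
    return np.array([states_s[i] for i in range(tree.n_tips)])


@dataclass
class DiploidGenotype:
    individual: str
    haplotypes: tuple[str, str]  # names of the two locus haplotypes


def simulate_locus_population(
    pool: list[HaplotypeArray],
    freqs: list[float],
    n_individuals: int,
    seed: int = 0,
    ensure_homozygotes: bool = False,
) -> list[DiploidGenotype]:
    """Hardy-Weinberg diploid draws from a pool of locus haplotypes.

    With ``ensure_homozygotes`` (requires ``n_individuals >= 3 * pool
    size``) the population is redrawn until every haplotype appears in at
    least one homozygote, mirroring the anchoring role homozygous
    individuals play in core-haplotype deduction.
    """
    freqs_arr = np.asarray(freqs, float)
    if abs(freqs_arr.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    if ensure_homozygotes and n_individuals < 3 * len(pool):
        raise ValueError("ensure_homozygotes requires n_individuals >= 3 * pool size")
    rng = np.random.default_rng(seed)
    names = [h.name for h in pool]
    while True:
        draws = rng.choice(len(pool), size=(n_individuals, 2), p=freqs_arr)
        if not ensure_homozygotes:
            break
        homo = {int(a) for a, b in draws if a == b}
        if homo == set(range(len(pool))):
            break
    return [
        DiploidGenotype(f"ind{i + 1:03d}", (names[int(a)], names[int(b)]))
        for i, (a, b) in enumerate(draws)
    ]


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def simulate_amplicon_reads(
    genotype: DiploidGenotype,
    pool: dict[str, HaplotypeArray],
    variant_sequences: dict[str, str],
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Amplicon reads for one individual, copy-number proportional.

    Reads are drawn from the union of both haplotypes' gene copies with
    probability proportional to copy number, then subjected to per-base
    substitution errors that create low-count artifact sequences.
    """
    labels: list[str] = []
    for hap_name in genotype.haplotypes:
        labels.extend(l.label for l in pool[hap_name].loci)
    missing = set(labels) - set(variant_sequences)
    if missing:
        raise ValueError(f"no sequence for variant label(s): {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if not labels:
        return []
    picks = rng.choice(len(labels), size=depth)
    return [_mutate(variant_sequences[labels[i]], error_rate, rng) for i in picks]


def simulate_qpcr_plate(
    true_copies: dict[str, float],
    populations: dict[str, str],
    calibrator: str,
    calibrator_copies: float = 1.0,
    noise_sd: float = 0.05,
    gene_noise_sd: float = 0.0,
    plate: str = "plate1",
    base_cq: float = 22.0,
    dct_baseline: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate multiplex Cq records for a set of individuals.

    Cq_control = base_cq + eps; Cq_target = base_cq + dct_baseline
    - log2(copies / calibrator_copies) + eps, with eps ~ N(0, noise_sd^2)
    drawn once per reaction: both genes share the reaction well, so well
    noise (template input, pipetting) is common to the multiplexed pair
    and cancels in the per-reaction dCt — the property the multiplex
    delta-delta-Ct design exploits. ``gene_noise_sd`` adds optional
    gene-independent noise that does propagate into dCt.

    ``true_copies`` must include the calibrator. A zero-copy individual
    yields missing target Cq (non-amplification).
    """
    if calibrator not in true_copies:
        raise ValueError("true_copies must include the calibrator")
    rng = np.random.default_rng(seed)
    rows = []
    for ind, copies in true_copies.items():
        for rep in (1, 2, 3):
            eps = rng.normal(0.0, noise_sd)
            cq_control = base_cq + eps + rng.normal(0.0, gene_noise_sd) if gene_noise_sd else base_cq + eps
            if copies > 0:
                cq_target = (
                    base_cq
                    + dct_baseline
                    - np.log2(copies / calibrator_copies)
                    + eps
                    + (rng.normal(0.0, gene_noise_sd) if gene_noise_sd else 0.0)
                )
            else:
                cq_target = np.nan
            rows.append(
                {
                    "individual": ind,
                    "population": populations.get(ind, "NA"),
                    "plate": plate,
                    "replicate": rep,
                    "cq_target": cq_target,
                    "cq_control": cq_control,
                }
            )
    return pd.DataFrame(rows)


def simulate_cluster_readpairs(
    variant_sequences: dict[str, str],
    expression: dict[str, float],
    n_pairs: int,
    read_len: int = 100,
    insert_len: int = 250,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Paired reads from a cluster of near-identical expressed gene copies.

    Pairs are drawn from variants proportional to relative expression;
    the insert is placed uniformly on the chosen variant; mate 1 is the
    forward strand prefix, mate 2 the reverse complement of the insert
    suffix. Substitution errors are applied per base.
    """
    names = sorted(variant_sequences)
    min_len = min(len(variant_sequences[n]) for n in names)
    if insert_len > min_len:
        raise ValueError("insert length exceeds the shortest variant")
    if read_len > insert_len:
        raise ValueError("read length exceeds insert length")
    probs = np.array([expression[n] for n in names], float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGTN", "TGCAN")
    pairs = []
    for _ in range(n_pairs):
        name = names[int(rng.choice(len(names), p=probs))]
        seq = variant_sequences[name]
        start = int(rng.integers(0, len(seq) - insert_len + 1))
        insert = seq[start : start + insert_len]
        r1 = _mutate(insert[:read_len], error_rate, rng)
        r2 = _mutate(insert[-read_len:].translate(comp)[::-1], error_rate, rng)
        pairs.append((r1, r2))
    return pairs
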