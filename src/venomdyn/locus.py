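"""Toxin-locus architecture: copy counting, tandem units, haplotype edits,
and non-B DNA motif scanning.

A locus haplotype is an ordered array of toxin gene copies (paralogs)
with orientations, coordinates (0-based half-open) and intergenic gaps.
Tandem duplication units — singlet, duplet or quadruplet blocks repeated
in place — are detected from label periodicity supported by consistent
intergenic spacing. Haplotypes are compared by the minimal number of
tandem block duplications / contiguous block deletions transforming one
label sequence into the other. Breakpoint neighborhoods are scanned for
inverted repeats and poly(G)/poly(C) runs, sequence features prone to
non-canonical (non-B) DNA structures implicated in deletion events.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from venomdyn.errors import VenomdynError

__all__ = [
    "Locus",
    "HaplotypeArray",
    "TandemUnit",
    "MotifHit",
    "count_copies",
    "flag_pseudogene",
    "detect_tandem_units",
    "compare_haplotypes",
    "scan_nonb_motifs",
    "breakpoint_context",
    "read_locus_tsv",
]

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Locus:
    label: str
    strand: str  # '+' or '-'
    start: int
    end: int
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.end <= self.start:
            raise ValueError("empty or inverted locus interval")


@dataclass
class HaplotypeArray:
    """Ordered, non-overlapping toxin gene copies of one locus haplotype."""

    name: str
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.loci, self.loci[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"{self.name}: loci overlap or are unsorted at {prev.label}/{nxt.label}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l.label for l in self.loci)

    @property
    def gaps(self) -> list[int]:
        """Intergenic gap (bp) between consecutive loci."""
        return [n.start - p.end for p, n in zip(self.loci, self.loci[1:])]


@dataclass
class TandemUnit:
    unit: tuple[str, ...]
    repeats: int
    start_index: int  # locus index of the first unit copy
    gap_score: float  # mean relative gap deviation across the span

    @property
    def span(self) -> tuple[int, int]:
        return (self.start_index, self.start_index + len(self.unit) * self.repeats)


def read_locus_tsv(path_or_buf) -> list[HaplotypeArray]:
    """Read a BED-like locus table: haplotype, label, strand, start, end, pseudogene."""
    df = pd.read_csv(path_or_buf, sep="\t")
    arrays = []
    for hap, grp in df.groupby("haplotype", sort=False):
        grp = grp.sort_values("start")
        loci = [
            Locus(str(r.label), str(r.strand), int(r.start), int(r.end), bool(r.pseudogene))
            for r in grp.itertuples()
        ]
        arrays.append(HaplotypeArray(str(hap), loci))
    return arrays


def count_copies(h: HaplotypeArray, include_pseudogenes: bool = True) -> int:
    """Number of gene copies, optionally excluding pseudogene-flagged loci."""
    if include_pseudogenes:
        return len(h.loci)
    return sum(1 for l in h.loci if not l.pseudogene)


def flag_pseudogene(
    cds: str, expected_mature_length: int, truncation_fraction: float = 0.8
) -> tuple[bool, str]:
    """Flag a gene copy as a pseudogene.

    True when the coding sequence has no ATG start, contains a stop codon
    before the final codon, or encodes a peptide shorter than
    ``truncation_fraction`` of the expected mature length.
    """
    cds = cds.upper()
    start = cds.find("ATG")
    if start < 0:
        return True, "no ORF"
    orf = cds[start:]
    orf = orf[: len(orf) - len(orf) % 3]
    codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in _STOPS:
            return True, "premature stop"
    length = len(codons) - (1 if codons and codons[-1] in _STOPS else 0)
    if length < truncation_fraction * expected_mature_length:
        return True, "truncated"
    return False, "intact"


def _gaps_consistent(g1: float, g2: float, rel_tol: float, abs_tol: float) -> bool:
    return abs(g1 - g2) <= max(rel_tol * max(abs(g1), abs(g2)), abs_tol)


def detect_tandem_units(
    h: HaplotypeArray,
    gap_rel_tol: float = 0.2,
    gap_abs_tol: float = 500.0,
) -> list[TandemUnit]:
    """Detect tandem duplication units from label periodicity and spacing.

    For each period u (1..n//2) and start, extend the maximal run where
    ``label[i] == label[i+u]`` and the corresponding intergenic gaps agree
    within ``max(gap_rel_tol * gap, gap_abs_tol)``. Maximal runs covering
    at least two full unit copies are reported as non-overlapping units,
    preferring smaller periods, then longer spans, then smaller starts.
    """
    labels = h.labels
    gaps = h.gaps
    n = len(labels)
    candidates: list[TandemUnit] = []
    for u in range(1, n // 2 + 1):
        # position j matches j+u when labels agree and the gap after j
        # mirrors the gap after j+u (when both exist)
        match = [
            labels[j] == labels[j + u]
            and (
                j >= len(gaps)
                or j + u >= len(gaps)
                or _gaps_consistent(gaps[j], gaps[j + u], gap_rel_tol, gap_abs_tol)
            )
            for j in range(n - u)
        ]
        for i in range(n - u):
            run = 0
            while i + run < n - u and match[i + run]:
                run += 1
            if run >= u:  # at least two full unit copies from this start
                repeats = run // u + 1
                devs = []
                for k in range(i, i + (repeats - 1) * u):
                    if k < len(gaps) and k + u < len(gaps):
                        g1, g2 = gaps[k], gaps[k + u]
                        denom = max(abs(g1), abs(g2), 1)
                        devs.append(abs(g1 - g2) / denom)
                score = sum(devs) / len(devs) if devs else 0.0
                candidates.append(TandemUnit(labels[i : i + u], repeats, i, score))
    # greedy non-overlapping selection: smaller period, longer span, smaller start
    candidates.sort(key=lambda t: (len(t.unit), -(t.span[1] - t.span[0]), t.start_index))
    chosen: list[TandemUnit] = []
    covered: set[int] = set()
    for cand in candidates:
        rng = set(range(*cand.span))
        if rng & covered:
            continue
        chosen.append(cand)
        covered |= rng
    chosen.sort(key=lambda t: t.start_index)
    return chosen


def compare_haplotypes(
    a: HaplotypeArray | tuple[str, ...],
    b: HaplotypeArray | tuple[str, ...],
    max_events: int = 6,
) -> tuple[int | None, list[str]]:
    """Minimal tandem-duplication/deletion event count between label arrays.

    Breadth-first search over label sequences where one event is either a
    tandem block duplication (a contiguous run copied in place) or a
    contiguous block deletion. Returns (count, one optimal event script);
    count is None when ``b`` is unreachable within ``max_events``.
    """
    sa = a.labels if isinstance(a, HaplotypeArray) else tuple(a)
    sb = b.labels if isinstance(b, HaplotypeArray) else tuple(b)
    if sa == sb:
        return 0, []
    if sb == ():
        # only a single full deletion reaches the zero-copy haplotype
        return (1, [f"delete [0:{len(sa)}) {'-'.join(sa)}"]) if max_events >= 1 else (None, [])
    seen = {sa}
    queue = deque([(sa, [])])
    while queue:
        state, script = queue.popleft()
        if len(script) >= max_events:
            continue
        n = len(state)
        moves: list[tuple[tuple[str, ...], str]] = []
        for i in range(n):
            for j in range(i + 1, n + 1):
                block = state[i:j]
                moves.append(
                    (state[:j] + block + state[j:], f"duplicate [{i}:{j}) {'-'.join(block)}")
                )
                if j - i < n:  # deleting everything only if target is empty
                    moves.append((state[:i] + state[j:], f"delete [{i}:{j}) {'-'.join(block)}"))
        if n == 0 and sb:
            continue
        for nxt, op in moves:
            if len(nxt) > 2 * max(len(sb), len(sa)) + 2:
                continue  # prune runaway growth
            if nxt == sb:
                return len(script) + 1, script + [op]
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, script + [op]))
    return None, []


@dataclass
class MotifHit:
    kind: str  # 'inverted_repeat' | 'polyG' | 'polyC'
    start: int
    end: int
    partner: tuple[int, int] | None = None  # second arm for inverted repeats

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_nonb_motifs(
    seq: str,
    min_arm: int = 6,
    max_loop: int = 100,
    min_g_run: int = 8,
) -> list[MotifHit]:
    """Scan for non-B DNA motifs: exact inverted repeats and poly(G)/(C) runs.

    Inverted repeats are reported as maximal (non-extendable) arm pairs
    with arm length >= ``min_arm`` and loop (separation) <= ``max_loop``;
    homopolymer G or C runs of length >= ``min_g_run`` are reported as
    maximal intervals.
    """
    seq = seq.upper()
    n = len(seq)
    hits: list[MotifHit] = []

    # homopolymer runs
    for base, kind in (("G", "polyG"), ("C", "polyC")):
        i = 0
        while i < n:
            if seq[i] == base:
                j = i
                while j < n and seq[j] == base:
                    j += 1
                if j - i >= min_g_run:
                    hits.append(MotifHit(kind, i, j))
                i = j
            else:
                i += 1

    # inverted repeats: seed on min_arm-mers, extend to maximality
    k = min_arm
    seeds: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        seeds.setdefault(seq[i : i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()  # (start1, start2, arm)
    for i in range(n - k + 1):
        word = seq[i : i + k]
        for j in seeds.get(_revcomp(word), ()):
            if j < i + k:  # arms must not overlap; enforce order
                continue
            # extend outward (left of i, right of j+k) and inward
            a1, a2, arm = i, j, k
            while a1 > 0 and a2 + arm < n and seq[a1 - 1] == _revcomp(seq[a2 + arm])[0]:
                a1 -= 1
                arm += 1
            while a1 + arm < a2 and seq[a1 + arm] == _revcomp(seq[a2 - 1])[0]:
                a2 -= 1
                arm += 1
            loop = a2 - (a1 + arm)
            if loop < 0 or loop > max_loop:
                continue
            key = (a1, a2, arm)
            if key in found:
                continue
            # keep only maximal pairs: no extension possible (checked above)
            found.add(key)
    for a1, a2, arm in sorted(found):
        hits.append(MotifHit("inverted_repeat", a1, a1 + arm, partner=(a2, a2 + arm)))
    hits.sort(key=lambda h: (h.start, h.end, h.kind))
    return hits


def breakpoint_context(
    breakpoints: list[int],
    motif_hits: list[MotifHit],
    seq_length: int,
    window: int = 500,
) -> dict[int, list[tuple[MotifHit, int]]]:
    """Motifs overlapping [pos - window, pos + window) per breakpoint.

    Each entry carries the signed distance from the breakpoint to the
    nearest motif edge: 0 when the breakpoint lies inside the motif,
    negative when the motif ends left of it, positive to the right.
    """
    out: dict[int, list[tuple[MotifHit, int]]] = {}
    for pos in breakpoints:
        if not 0 <= pos < seq_length:
            raise VenomdynError(f"breakpoint {pos} outside sequence of length {seq_length}")
        lo, hi = pos - window, pos + window
        nearby = []
        for hit in motif_hits:
            intervals = [hit.interval] + ([hit.partner] if hit.partner else [])
            for s, e in intervals:
                if e > lo and s < hi:
                    if s <= pos < e:
                        dist = 0
                    elif e <= pos:
                        dist = e - 1 - pos  # negative: motif left of breakpoint
                    else:
                        dist = s - pos
                    nearby.append((hit, dist))
                    break
        out[pos] = nearby
    return out
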