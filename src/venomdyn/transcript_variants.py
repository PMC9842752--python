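"""Recovery of sequence variants of a highly duplicated toxin gene.

The Nv1 cluster contains many near-identical gene copies, so reads from
all copies map to a single collapsed gene model. Each mapped read pair is
turned into a consensus sequence on gene-model coordinates; identical
consensi are clustered; and clusters are retained when they either fall
in the most-abundant prefix accounting for 70% of all sequences or carry
at least 10 identical copies. An Nv3-vs-Nv1 diagnostic motif classifies
sequences between the two closely related genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from venomdyn.errors import VenomdynError

__all__ = [
    "ReadPairConsensus",
    "VariantCluster",
    "align_pair_to_model",
    "cluster_identical",
    "retain_variants",
    "detect_nv3_signature",
    "NV3_MOTIF",
    "NV1_MOTIF",
]

# Diagnostic codons distinguishing the two paralogous genes: the Nv3
# signature encodes KRGFA where Nv1 encodes KRGIP.
NV3_MOTIF = "AAACGCGGCTTTGCT"
NV1_MOTIF = "AAACGCGGCATTCCT"


@dataclass
class ReadPairConsensus:
    """Consensus of one read pair placed on gene-model coordinates."""

    sequence: str  # over ACGTN, length == end - start
    start: int  # covered interval, 0-based half-open
    end: int
    conflicts: int  # overlap positions where the mates disagreed

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("consensus length must equal covered interval length")


@dataclass
class VariantCluster:
    sequence: str
    count: int
    retained: bool = False


def _make_aligner() -> Align.PairwiseAligner:
    # global in the read, local in the model: end gaps in the model are free
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps opposite the model flanks (local in the model)
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _place_read(read: str, model: str) -> tuple[dict[int, str], float] | None:
    """Best-strand placement of a read on the model.

    Returns (model position -> base, identity) or None when the best
    alignment identity over aligned read bases falls below 90%.
    """
    best = None
    for seq in (read, _revcomp(read)):
        aln = _ALIGNER.align(model, seq)[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, aln, seq)
    _, aln, seq = best
    reverse = seq != read
    placed: dict[int, tuple[str, int]] = {}  # model pos -> (base, read offset)
    matches = 0
    aligned = 0
    n = len(read)
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            base = seq[q0 + off]
            # map back to the original read coordinate for quality lookup
            read_off = (n - 1 - (q0 + off)) if reverse else (q0 + off)
            placed[t0 + off] = (base, read_off)
            aligned += 1
            if base == model[t0 + off]:
                matches += 1
    if aligned == 0 or matches / aligned < 0.90:
        return None
    return placed, matches / aligned


def align_pair_to_model(
    read1: str,
    read2: str,
    model: str,
    qual1: list[int] | None = None,
    qual2: list[int] | None = None,
) -> ReadPairConsensus | None:
    """Consensus of a read pair on the collapsed gene model.

    Each mate is placed by glocal alignment (both strands tried; identity
    >= 90% required, mirroring mapper acceptance). The consensus covers
    the union interval; uncovered interior positions emit N. Where the
    mates overlap and disagree, the base with the higher quality wins if
    qualities are given, otherwise an N is emitted; disagreements are
    counted as conflicts.
    """
    read1, read2, model = read1.upper(), read2.upper(), model.upper()
    p1 = _place_read(read1, model)
    p2 = _place_read(read2, model)
    if p1 is None or p2 is None:
        return None
    placed1, _ = p1
    placed2, _ = p2

    positions = set(placed1) | set(placed2)
    start, end = min(positions), max(positions) + 1
    bases = []
    conflicts = 0
    for pos in range(start, end):
        e1, e2 = placed1.get(pos), placed2.get(pos)
        if e1 is None and e2 is None:
            bases.append("N")
        elif e1 is None:
            bases.append(e2[0])
        elif e2 is None:
            bases.append(e1[0])
        elif e1[0] == e2[0]:
            bases.append(e1[0])
        else:
            conflicts += 1
            q1 = qual1[e1[1]] if qual1 is not None else None
            q2 = qual2[e2[1]] if qual2 is not None else None
            if q1 is not None and q2 is not None and q1 != q2:
                bases.append(e1[0] if q1 > q2 else e2[0])
            else:
                bases.append("N")
    return ReadPairConsensus("".join(bases), start, end, conflicts)


def cluster_identical(
    consensi: list[ReadPairConsensus], region: tuple[int, int]
) -> tuple[list[VariantCluster], int]:
    """Exact-string clustering of consensi trimmed to a common region.

    Consensi not fully covering ``region`` or containing N inside it are
    discarded (their number is returned). Clusters are sorted by count
    descending, ties broken lexicographically by sequence.
    """
    lo, hi = region
    discarded = 0
    counter: Counter[str] = Counter()
    for c in consensi:
        if c.start > lo or c.end < hi:
            discarded += 1
            continue
        s = c.sequence[lo - c.start : hi - c.start]
        if "N" in s:
            discarded += 1
            continue
        counter[s] += 1
    clusters = [VariantCluster(seq, n) for seq, n in counter.items()]
    clusters.sort(key=lambda c: (-c.count, c.sequence))
    return clusters, discarded


def retain_variants(
    clusters: list[VariantCluster],
    retention_fraction: float = 0.70,
    min_copies: int = 10,
) -> list[VariantCluster]:
    """Apply the abundance retention rule (in place; clusters must be sorted).

    Retained = union of (a) the shortest prefix of the count-sorted list
    whose cumulative count reaches ``retention_fraction`` of the total and
    (b) every cluster with at least ``min_copies`` identical copies.
    """
    total = sum(c.count for c in clusters)
    cum = 0
    prefix_done = False
    for c in clusters:
        in_prefix = False
        if not prefix_done:
            in_prefix = True
            cum += c.count
            if cum >= retention_fraction * total:
                prefix_done = True
        c.retained = in_prefix or c.count >= min_copies
    return clusters


def detect_nv3_signature(seq: str) -> str:
    """Classify a nucleotide sequence as ``"Nv3"``, ``"Nv1"`` or ``"neither"``
    by the diagnostic signature motif; both motifs present is an error."""
    seq = seq.upper()
    has3 = NV3_MOTIF in seq
    has1 = NV1_MOTIF in seq
    if has3 and has1:
        raise VenomdynError("sequence contains both Nv1 and Nv3 signature motifs")
    if has3:
        return "Nv3"
    if has1:
        return "Nv1"
    return "neither"
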