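"""Venom expression phenotype: toxin-family composition and dominance.

The phenotype of a sample is the vector of toxin-family fractions of its
total toxin expression: per-family cumulative TPM divided by the summed
TPM of all annotated toxin transcripts. A family is *dominant* when its
fraction strictly exceeds the dominance threshold (default one half).
Cysteine frameworks — the spacing pattern of cysteines in a mature
peptide — support the conserved-framework check used when curating toxin
families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from venomdyn.errors import UndefinedCompositionError

__all__ = [
    "FamilyComposition",
    "aggregate_family_expression",
    "classify_dominant",
    "species_composition",
    "cysteine_framework",
    "framework_match",
]


@dataclass
class FamilyComposition:
    """Per-sample toxin-family cumulative TPM and fractions."""

    sample: str
    tpm: pd.Series  # family -> cumulative TPM
    fractions: pd.Series | None = field(default=None)  # None when undefined

    @property
    def defined(self) -> bool:
        return self.fractions is not None

    def __post_init__(self) -> None:
        if (self.tpm < 0).any():
            raise ValueError("negative family TPM")
        if self.fractions is not None:
            total = float(self.fractions.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {total}, not 1")


def aggregate_family_expression(
    expr: pd.DataFrame,
    annot: pd.Series,
    families: list[str] | None = None,
) -> list[FamilyComposition]:
    """Sum TPM per toxin family and convert to fractions, per sample.

    Parameters
    ----------
    expr:
        sample x transcript TPM table; transcripts absent from ``annot``
        are ignored.
    annot:
        transcript -> family map; every annotated transcript must be
        present in ``expr``.
    families:
        Optional declared family set; families without transcripts get 0.

    A sample whose total annotated TPM is zero yields an *undefined*
    composition (``fractions is None``).
    """
    missing = set(annot.index) - set(expr.columns)
    if missing:
        raise ValueError(f"annotated transcripts missing from expression: {sorted(missing)}")
    fams = list(families) if families is not None else sorted(set(annot.values))
    sub = expr[annot.index]
    out = []
    for sample, row in sub.iterrows():
        tpm = row.groupby(annot).sum().reindex(fams, fill_value=0.0)
        total = float(tpm.sum())
        if total > 0:
            comp = FamilyComposition(str(sample), tpm, tpm / total)
        else:
            warnings.warn(f"sample {sample!r}: total annotated TPM is zero; composition undefined")
            comp = FamilyComposition(str(sample), tpm, None)
        out.append(comp)
    return out


def classify_dominant(comp: FamilyComposition, threshold: float = 0.5) -> str:
    """Return the family whose fraction strictly exceeds ``threshold``, else ``"none"``."""
    if not comp.defined:
        raise UndefinedCompositionError(f"sample {comp.sample!r} has undefined composition")
    top = comp.fractions.idxmax()
    if comp.fractions[top] > threshold:
        return str(top)
    return "none"


def species_composition(comps: list[FamilyComposition]) -> FamilyComposition:
    """Pool samples of one species: mean of sample fractions, renormalized."""
    defined = [c for c in comps if c.defined]
    if not defined:
        raise UndefinedCompositionError("no defined compositions to pool")
    frac = pd.concat([c.fractions for c in defined], axis=1).mean(axis=1)
    frac = frac / frac.sum()
    tpm = pd.concat([c.tpm for c in defined], axis=1).sum(axis=1)
    return FamilyComposition("+".join(c.sample for c in defined), tpm, frac)


def composition_table(comps: list[FamilyComposition], threshold: float = 0.5) -> pd.DataFrame:
    """Long-format table: sample, family, tpm, fraction, dominant flag."""
    rows = []
    for c in comps:
        dom = classify_dominant(c, threshold) if c.defined else "undefined"
        for fam in c.tpm.index:
            rows.append(
                {
                    "sample": c.sample,
                    "family": fam,
                    "tpm": c.tpm[fam],
                    "fraction": c.fractions[fam] if c.defined else np.nan,
                    "dominant": fam == dom,
                }
            )
    return pd.DataFrame(rows)


def cysteine_framework(peptide: str) -> str:
    """Encode the cysteine spacing of a peptide as ``C<g1>C<g2>...C``.

    ``gi`` is the number of residues between consecutive cysteines; a
    peptide with no cysteine yields the empty framework.
    """
    peptide = peptide.upper()
    positions = [i for i, aa in enumerate(peptide) if aa == "C"]
    if not positions:
        return ""
    parts = ["C"]
    for prev, nxt in zip(positions, positions[1:]):
        parts.append(str(nxt - prev - 1))
        parts.append("C")
    return "".join(parts)


def _gaps(framework: str) -> list[int]:
    inner = framework.strip("C")
    return [int(g) for g in inner.split("C")] if inner else []


def framework_match(a: str, b: str, gap_tolerance: int = 0) -> bool:
    """True iff the two frameworks have equal cysteine counts and every
    inter-cysteine gap differs by at most ``gap_tolerance`` residues."""
    if not a or not b:
        warnings.warn("empty cysteine framework in comparison")
        return False
    if a.count("C") != b.count("C"):
        return False
    return all(abs(x - y) <= gap_tolerance for x, y in zip(_gaps(a), _gaps(b)))
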