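"""Pipeline configuration: every stated threshold in one place.

The defaults encode the filtering and quantification constants of the
study protocol: amplicons are kept between 300 and 500 bp, samples are
subsampled to 14,800 reads, a sequence is a biological variant if it
reaches 100 reads in some individual and occurs in more than one
individual, transcriptomic variant clusters are retained by the 70% /
10-identical-copies rule, qPCR triplicates must agree within 0.2 Cq, and
the reference calibrator is defined to carry one diploid copy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis pipeline.

    Attributes
    ----------
    dominance_threshold:
        Fraction of total toxin expression a family must exceed (strictly)
        to be called the dominant family.
    amplicon_min_len, amplicon_max_len:
        Inclusive length bounds (bp) for amplicon size filtering.
    subsample_depth:
        Number of reads drawn per sample; shallower samples are excluded.
    variant_min_abundance:
        Read count a sequence must reach in at least one individual.
    variant_min_individuals:
        Number of individuals a sequence must occur in to be a variant.
    retention_fraction:
        Cumulative-abundance prefix used when retaining transcriptomic
        variant clusters.
    min_identical_copies:
        Alternative retention route: clusters with at least this many
        identical copies are kept regardless of the prefix rule.
    cq_tolerance:
        Maximum pairwise Cq deviation tolerated within a triplicate.
    calibrator_copies:
        Diploid copy number assigned to the reference calibrator.
    bootstrap_replicates:
        Parametric-bootstrap replicates for covariance intervals.
    seed:
        Default seed for every randomized operation.
    """

    dominance_threshold: float = 0.5
    amplicon_min_len: int = 300
    amplicon_max_len: int = 500
    subsample_depth: int = 14_800
    variant_min_abundance: int = 100
    variant_min_individuals: int = 2
    retention_fraction: float = 0.70
    min_identical_copies: int = 10
    cq_tolerance: float = 0.2
    calibrator_copies: float = 1.0
    bootstrap_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dominance_threshold",
            "amplicon_min_len",
            "amplicon_max_len",
            "subsample_depth",
            "variant_min_abundance",
            "variant_min_individuals",
            "retention_fraction",
            "min_identical_copies",
            "cq_tolerance",
            "calibrator_copies",
            "bootstrap_replicates",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name in ("dominance_threshold", "retention_fraction"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.amplicon_min_len > self.amplicon_max_len:
            raise ValueError("amplicon_min_len must not exceed amplicon_max_len")

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        """Build a config from a JSON object; unknown keys are rejected."""
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
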