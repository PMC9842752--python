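"""Exception types shared across the pipeline."""


class VenomdynError(Exception):
    """Base class for all package errors."""


class NewickParseError(VenomdynError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, missing lengths)."""


class FastaFormatError(VenomdynError):
    """Malformed FASTA input (empty record, non-IUPAC character)."""


class UndefinedCompositionError(VenomdynError):
    """A family composition with zero total annotated TPM has no fractions."""


class NotUltrametricError(VenomdynError):
    """An operation requiring an ultrametric tree received one that is not."""


class CalibratorMissingError(VenomdynError):
    """The qPCR reference calibrator sample is absent from the plate data."""


class MixtureOverflowError(VenomdynError):
    """Jump-normal mixture pruning exceeded its component budget."""
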