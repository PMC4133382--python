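"""Exception hierarchy shared across the package."""


class NitropredError(Exception):
    """Base class for all package errors."""


class FormatError(NitropredError):
    """Malformed input text (FASTA, benchmark TSV, model file)."""


class DataError(NitropredError):
    """Structurally valid input that violates a data contract
    (e.g. an annotated position that is not a tyrosine)."""


class ContractError(NitropredError):
    """Incompatible objects passed to an operation (e.g. mismatched
    window half-widths)."""


class EstimationError(NitropredError):
    """A propensity matrix or model cannot be estimated (empty class)."""


class EvaluationError(NitropredError):
    """Invalid cross-validation setup (class too small, single-class
    scores, bad fold count)."""
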