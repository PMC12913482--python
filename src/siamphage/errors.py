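"""Exception hierarchy: configuration vs data vs protocol problems.

The CLI maps these onto distinct exit codes, so scripted callers can tell a
bad config from a bad input file from a train/test-hygiene violation.
"""


class SiamphageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SiamphageError):
    """Invalid or inconsistent configuration values."""


class DataError(SiamphageError):
    """Malformed or incomplete input data (FASTA, tables, lookups)."""


class FormatError(DataError):
    """A file does not parse as the expected format."""


class ContractError(SiamphageError):
    """An internal shape/precondition contract was violated."""


class ProtocolError(SiamphageError):
    """Evaluation-protocol violation, e.g. train/test overlap."""


class SamplingInfeasibleError(DataError):
    """Requested sampling constraints cannot be satisfied by the data."""


class TrainingError(SiamphageError):
    """Numerical failure during optimisation (NaN/Inf gradients or loss)."""
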