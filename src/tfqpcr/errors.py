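"""Exception hierarchy for the qRT-PCR analysis pipeline."""


class TfqpcrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TfqpcrError, ValueError):
    """A tabular input file does not match the expected layout."""


class CtRangeError(TfqpcrError, ValueError):
    """A quantification-cycle value lies outside (0, ceiling]."""


class DuplicateRecordError(TfqpcrError, ValueError):
    """More than one Ct record for the same (gene, sample)."""


class MissingReferenceError(TfqpcrError, KeyError):
    """A PCR run has no reference-gene wells."""


class ConfigError(TfqpcrError, ValueError):
    """Invalid generator or analysis configuration."""
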