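"""Exception hierarchy shared across the pipeline stages."""


class ResistSeqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ResistSeqError):
    """Invalid configuration value; the message names the offending field."""


class DataError(ResistSeqError):
    """Malformed or inconsistent input data."""


class TrainingError(ResistSeqError):
    """Model training failed (e.g. non-finite loss)."""


class SelectionError(ResistSeqError):
    """Model selection is impossible (e.g. single-class selection labels)."""
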