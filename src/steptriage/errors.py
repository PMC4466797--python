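"""Exception hierarchy for the triage pipeline."""


class TriageError(Exception):
    """Base class for all package errors."""


class ValidationError(TriageError):
    """Invalid user input: malformed records, mismatched shapes, bad parameters."""


class ConfigurationError(TriageError):
    """Invalid configuration: unknown fragment names, non-compiling SMARTS, missing files."""


class DegenerateDataError(TriageError):
    """Data that cannot support the requested computation (e.g. a single-class training set)."""
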