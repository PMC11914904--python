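"""Exception hierarchy shared across the pipeline stages."""


class AuxopepError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AuxopepError):
    """A file could not be parsed under its declared format."""


class ValidationError(AuxopepError):
    """An in-memory object violates one of its structural invariants.

    Carries the full list of violations so callers can report them all
    at once instead of fixing one at a time.
    """

    def __init__(self, failures):
        if isinstance(failures, str):
            failures = [failures]
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class InputError(AuxopepError):
    """Caller-supplied arguments are out of contract (bad thresholds,
    unknown identifiers, empty inputs where data is required)."""
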