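"""Exception hierarchy shared across the package."""


class PairedomicsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PairedomicsError, ValueError):
    """A record or value violates a documented invariant."""


class FormatError(PairedomicsError, ValueError):
    """A file does not conform to the expected tabular format."""


class ConfigError(PairedomicsError, ValueError):
    """A configuration object is internally inconsistent."""


class StageError(PairedomicsError, RuntimeError):
    """A pipeline stage failed after validation succeeded."""
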