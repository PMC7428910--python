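"""Exception types shared across the pipeline."""


class ElmhError(Exception):
    """Base class for package errors."""


class ConfigurationError(ElmhError, ValueError):
    """An invalid configuration field; the message names the field."""


class InputError(ElmhError, ValueError):
    """Malformed respondent input (wrong length, out-of-range values)."""


class EstimationError(ElmhError, RuntimeError):
    """A model fit cannot proceed (degenerate or singular data)."""


class GeometryError(ElmhError, ValueError):
    """An inconsistent network geometry (non-dividing pooling etc.)."""
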