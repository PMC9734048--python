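"""Exception types shared across the pipeline stages."""


class NeuroflexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeuroflexError, ValueError):
    """A configuration value or combination of values is invalid."""


class InsufficientDataError(NeuroflexError, ValueError):
    """Too few timepoints, layers or samples for the requested operation."""


class DegenerateModelError(NeuroflexError, ValueError):
    """A statistical model cannot be fit (rank deficiency, zero variance)."""


class UndefinedQualityError(NeuroflexError, ValueError):
    """Multilayer modularity is undefined (no edge weight anywhere)."""


class ParseError(NeuroflexError, ValueError):
    """An input file violates the documented format."""
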