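"""Exception hierarchy shared across the pipeline stages."""


class LncModNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LncModNetError):
    """A configuration value violates its documented range or invariant."""


class InputError(LncModNetError):
    """An input table or file violates the expected schema or contract."""


class UndefinedAssociationError(LncModNetError):
    """Association index undefined (empty or universe-sized correlated set)."""


class InsufficientDataError(LncModNetError):
    """Too few observations for the requested estimate."""


class FitError(LncModNetError):
    """A model fit failed to converge or is degenerate."""


class DegenerateSplitError(LncModNetError):
    """Median split impossible because all values coincide."""
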