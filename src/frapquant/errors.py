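"""Exception hierarchy shared across the package."""


class FrapQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrapQuantError):
    """A simulation or pipeline configuration is invalid or unsatisfiable."""


class DataError(FrapQuantError):
    """Input data violate a precondition (shapes, signs, missing frames...)."""


class UnsupportedDesignError(DataError):
    """A statistical design the package deliberately refuses to approximate
    (e.g. unbalanced two-way layouts)."""
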