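"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class CatalogError(ValidationError):
    """Raised for malformed cohort catalogs (bad header, duplicate ranks, ...)."""
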