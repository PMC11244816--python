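"""Exception types shared across the package."""


class NeoquadError(Exception):
    """Base class for all package-specific errors."""


class InvalidRecordError(NeoquadError):
    """A death record violates a structural precondition (e.g. death before birth)."""


class PostNeonatalDeath(NeoquadError):
    """Age at death exceeds 672 completed hours; the death is not neonatal."""


class SingularDesignError(NeoquadError):
    """Too few distinct NMR values to identify the quadratic regression."""


class NoDeviationSignal(NeoquadError):
    """Residual matrix is numerically zero; no deviation vector can be estimated."""


class DegenerateDeviation(NeoquadError):
    """Deviation vector vanishes at the last cumulative age; k is unidentifiable."""
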