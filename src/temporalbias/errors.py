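"""Exception hierarchy for the temporalbias package."""


class TemporalBiasError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TemporalBiasError, ValueError):
    """A generator or model parameter violates its constraints."""


class InvalidInputError(TemporalBiasError, ValueError):
    """An input object (table, array, spec) violates its invariants."""


class EstimationError(TemporalBiasError, RuntimeError):
    """A model fit failed (perfect separation, non-convergence,
    single-class outcome, degenerate design)."""


class MatchingError(TemporalBiasError, RuntimeError):
    """Case-control matching exhausted its strata beyond tolerance."""
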