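"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or numerical parameter violates its domain (e.g. a
    nonpositive time scale or gravity level)."""


class NumericalStabilityError(RuntimeError):
    """The explicit time integration blew up; the message names the
    offending time step so the caller can refine it."""


class ContractError(RuntimeError):
    """An internal precondition was violated (missing history, mismatched
    replicate pairing, ...)."""
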