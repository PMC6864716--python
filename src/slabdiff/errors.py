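"""Exception hierarchy for slabdiff."""


class SlabdiffError(Exception):
    """Base class for all slabdiff errors."""


class DomainError(SlabdiffError, ValueError):
    """A physical argument lies outside its valid range (x outside the gel, t < 0, ...)."""


class ConfigurationError(SlabdiffError, ValueError):
    """A scenario, config or calibration object is inconsistent with the requested operation."""


class IdentifiabilityError(SlabdiffError, ValueError):
    """The measurement layout cannot constrain the requested parameters."""


class InfeasibleDesignError(SlabdiffError, ValueError):
    """The design target cannot be reached (e.g. target mean >= bath concentration)."""


class SolverError(SlabdiffError, RuntimeError):
    """The numerical solver produced non-finite values or failed to converge."""
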