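"""Exception types raised by the simulator and analysis routines."""


class CritmemError(Exception):
    """Base class for package-specific errors."""


class FitError(CritmemError):
    """The avalanche size distribution is too degenerate to fit a power law."""


class NonConvergenceError(CritmemError):
    """A criticalization loop exceeded its round budget.

    Carries the last measured goodness-of-fit statistic so callers can
    diagnose whether the mechanism was making progress at all.
    """

    def __init__(self, message: str, last_delta_gamma: float | None = None):
        super().__init__(message)
        self.last_delta_gamma = last_delta_gamma


class NormalizationError(CritmemError):
    """The raw memory matrix sums to zero and cannot be normalized."""


class UndefinedOverlapError(CritmemError):
    """Overlap requested for a constant (all-zero or all-one) activity vector."""
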