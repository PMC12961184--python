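"""Exception hierarchy for curefollowup."""


class CureFollowupError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CureFollowupError, ValueError):
    """Raised when input data or configuration violates a precondition."""


class OutOfRangeError(CureFollowupError, ValueError):
    """Raised when an evaluation point falls outside the admissible region."""


class DegenerateBoundaryError(CureFollowupError, ValueError):
    """Raised when the boundary-kernel moment system is singular."""


class DegenerateDensityError(CureFollowupError, ValueError):
    """Raised when a density estimate degenerates to zero and the test
    statistic can no longer be calibrated."""


class InvalidBandwidthError(CureFollowupError, ValueError):
    """Raised when a bandwidth is too large for the boundary-kernel
    construction (left and right boundary branches would overlap)."""
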