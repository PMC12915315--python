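"""Exception hierarchy shared by all crisedit modules."""


class CrisEditError(Exception):
    """Base class for all crisedit errors."""


class AlphabetError(CrisEditError, ValueError):
    """Sequence contains characters outside the accepted alphabet."""


class DuplicateIdError(CrisEditError, ValueError):
    """Two records share an identifier that must be unique."""


class OutOfBoundsError(CrisEditError, ValueError):
    """Interval extends beyond a linear sequence."""


class BoundsError(OutOfBoundsError):
    """Feature location outside the sequence being emitted."""


class LengthError(CrisEditError, ValueError):
    """Sequence length violates an operation's length contract."""


class EmptyWindowWarning(UserWarning):
    """Candidate window too small to hold PAM plus protospacer."""


class InsufficientCandidates(CrisEditError):
    """Fewer admissible guide candidates than requested.

    ``reasons`` maps each rejected candidate's name to why it was rejected.
    """

    def __init__(self, needed: int, admissible: int, reasons: dict):
        self.needed = needed
        self.admissible = admissible
        self.reasons = dict(reasons)
        detail = "; ".join(f"{k}: {v}" for k, v in self.reasons.items())
        super().__init__(
            f"need {needed} spacers but only {admissible} admissible ({detail})"
        )


class DesignError(CrisEditError):
    """Deletion window cannot be placed (e.g. runs off the contig)."""


class FlankError(CrisEditError):
    """Not enough genomic flank for the requested homology arm length."""

    def __init__(self, requested: int, max_feasible: int):
        self.requested = requested
        self.max_feasible = max_feasible
        super().__init__(
            f"arm length {requested} infeasible; at most {max_feasible} bp of flank"
        )


class SiteError(CrisEditError):
    """Restriction site absent or not unique in the construct."""

    def __init__(self, motif: str, count: int):
        self.motif = motif
        self.count = count
        super().__init__(f"site {motif} occurs {count} times; exactly 1 required")


class PrimerError(CrisEditError):
    """No admissible primer found within the search span."""


class PlacementError(CrisEditError):
    """No room to plant a synthetic feature."""


class ConfigError(CrisEditError, ValueError):
    """Invalid configuration value; message names the failing field."""
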