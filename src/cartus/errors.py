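"""Exception hierarchy shared by all pipeline stages."""


class CartusError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CartusError, ValueError):
    """Invalid or degenerate contour geometry."""


class DegeneratePartitionError(GeometryError):
    """Central point too close to the cartilage extent edge: a region cut
    would fall outside the segmented extent."""


class ZeroAreaError(GeometryError):
    """Requested strip has no extent (empty clip)."""


class ZeroLengthError(GeometryError):
    """Requested strip yields no bone-interface length."""


class StatisticsError(CartusError, ValueError):
    """Invalid input to a statistical routine."""


class UndefinedICCError(StatisticsError):
    """ICC is undefined (zero total variance)."""


class UndefinedStatisticError(StatisticsError):
    """Test statistic undefined (e.g. zero variance in a t-test)."""


class InvalidSpecError(CartusError, ValueError):
    """Synthetic-data specification violates its invariants."""


class FormatError(CartusError, ValueError):
    """Malformed input file (ROI, CSV, mask, or sidecar)."""


class IncompleteParticipantError(CartusError, ValueError):
    """Longitudinal table missing required sessions for some participants."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "participants missing a required session: "
            + ", ".join(map(str, self.offenders))
        )
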