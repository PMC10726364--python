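"""Exception hierarchy shared across the package."""


class RingDynError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(RingDynError, ValueError):
    """Coincident or collinear defining atoms; indicates corrupt input."""


class InsufficientDataError(RingDynError, ValueError):
    """Too few frames, molecules, or states for the requested statistic."""


class SelectionError(RingDynError, ValueError):
    """A ring-atom selection could not be resolved against the topology."""


class FormatError(RingDynError, ValueError):
    """A trajectory file is structurally inconsistent (counts, models)."""


class UsageError(RingDynError, ValueError):
    """Invalid argument combination (bad format token, binning mismatch...)."""


class GenerationError(RingDynError, ValueError):
    """The synthetic generator was asked for an infeasible geometry."""


class EnumerationCapError(RingDynError, RuntimeError):
    """Projected charge-lattice enumeration exceeds the configured cap."""

    def __init__(self, projected: int, cap: int):
        self.projected = projected
        self.cap = cap
        super().__init__(
            f"charge-set enumeration would visit {projected} lattice points, "
            f"exceeding the cap of {cap}; raise the cap explicitly to proceed"
        )
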