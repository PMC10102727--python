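"""Exception hierarchy for brainrev."""


class BrainrevError(Exception):
    """Base class for all brainrev errors."""


class ValidationError(BrainrevError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(BrainrevError, ValueError):
    """A correlation segment has zero variance."""


class SeriesTooShortError(BrainrevError, ValueError):
    """Time series shorter than required by the requested operation."""


class InsufficientWindowsError(BrainrevError, ValueError):
    """Fewer sliding windows than a downstream summary requires."""


class StationarityError(BrainrevError, ValueError):
    """Coupling matrix would produce a non-stationary process."""


class PartitionError(BrainrevError, ValueError):
    """Invalid region-to-network partition request."""
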