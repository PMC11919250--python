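"""Exception types shared across the package."""


class IslandsegError(Exception):
    """Base class for all islandseg errors."""


class InvalidParameterError(IslandsegError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive voxel size)."""


class SwcFormatError(IslandsegError, ValueError):
    """An SWC file violates the format contract (multiple roots, orphans, cycles).

    Carries the 1-based line number of the offending record where applicable.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ColumnMappingError(IslandsegError, KeyError):
    """A required column of a synapse table cannot be resolved."""


class CircuitValidationError(IslandsegError, ValueError):
    """A Circuit violates its structural invariants."""


class UnresolvedSynapseError(IslandsegError, ValueError):
    """Synapses could not be assigned to skeleton nodes.

    ``synapse_ids`` lists the offending records.
    """

    def __init__(self, synapse_ids):
        self.synapse_ids = list(synapse_ids)
        super().__init__(
            "could not resolve synapses to skeleton nodes: "
            + ", ".join(map(str, self.synapse_ids))
        )


class UndefinedMetricError(IslandsegError, ValueError):
    """A metric is undefined for the given inputs (e.g. empty class or cohort)."""


class DegenerateLabelingWarning(UserWarning):
    """A labeling method produced a degenerate partition (one class empty)."""
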