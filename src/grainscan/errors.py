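"""Exception hierarchy shared across the pipeline stages."""


class GrainScanError(Exception):
    """Base class for all grainscan errors."""


class InvalidParameterError(GrainScanError, ValueError):
    """A configuration or profile parameter is out of its valid range."""


class InvalidInputError(GrainScanError, ValueError):
    """An input array/table does not satisfy an operation's precondition."""


class PlacementError(GrainScanError, RuntimeError):
    """Grain placement failed; carries how many grains were placed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} grains without overlap"
        )


class DegenerateHistogramError(GrainScanError, ValueError):
    """Histogram has fewer than two occupied intensity levels; no threshold
    can separate two classes."""


class NoMarkerError(GrainScanError, ValueError):
    """Watershed was called without any marker."""


class InvalidRegionError(GrainScanError, ValueError):
    """A grain region is empty, multi-component or otherwise degenerate."""


class DegenerateShapeError(InvalidRegionError):
    """Region is line-like (zero minor axis); ellipse fit undefined."""


class EmptyPairsError(InvalidRegionError):
    """No valid co-occurrence pixel pairs inside the mask for the offset."""


class InvalidDistributionError(GrainScanError, ValueError):
    """A matrix expected to be a normalized probability distribution is not."""


class StratificationError(GrainScanError, ValueError):
    """A class has too few samples for the requested fold count."""


class DegenerateTrainingError(GrainScanError, ValueError):
    """Training data contains a single class."""


class UnsupportedModelError(GrainScanError, TypeError):
    """Operation requires a tree-based model with feature importances."""


class MissingPriceError(GrainScanError, KeyError):
    """A predicted variety has no entry in the price table."""


class EmptyMixtureError(GrainScanError, ValueError):
    """Mixture counts sum to zero."""
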