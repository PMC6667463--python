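"""Exception hierarchy.

Every condition the analysis treats as a decision point (empty region after
erosion, too few surviving bins, collinear component library, ...) gets its
own type so callers can catch and record exclusions rather than silently
dropping regions.
"""


class MdmtvError(Exception):
    """Base class for all package errors."""


class ConfigError(MdmtvError):
    """Invalid run configuration (schema violation, unresolvable path)."""


class DataError(MdmtvError):
    """Malformed or inconsistent input data."""


class GridMismatchError(DataError):
    """Maps/labels do not share an identical voxel grid."""


class EmptyRegionError(DataError):
    """ROI is empty (possibly after erosion); caller decides exclusion."""


class InsufficientBinsError(MdmtvError):
    """Too few MTV bins survive the count filter to fit a line."""


class DegenerateRegressorError(MdmtvError):
    """Regressor has zero variance across surviving bins."""


class EmptySignatureError(MdmtvError):
    """Every requested qMRI parameter was excluded for a region."""


class CollinearLibraryError(MdmtvError):
    """Component slope matrix is rank-deficient; unmixing is ill-posed."""

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


class DegenerateVarianceError(MdmtvError):
    """Pooled standard deviation is zero; effect size undefined."""
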