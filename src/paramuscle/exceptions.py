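"""Exception hierarchy shared across the package."""


class ParamuscleError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ParamuscleError):
    """Image/mask geometry is invalid or inconsistent (shape, spacing)."""


class MaskLabelError(ParamuscleError):
    """A label mask contains values outside the expected label set."""


class MissingMetadataError(ParamuscleError):
    """A required header field (e.g. pixel spacing) is absent."""


class BiasFitError(ParamuscleError):
    """The polynomial bias-surface fit is ill-posed or non-positive."""


class DegenerateHistogramError(ParamuscleError):
    """All ROI intensities are identical; no threshold can be defined."""


class CollinearityError(ParamuscleError):
    """Exactly collinear covariates in a regression design."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"exactly collinear covariates: {self.columns}")
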