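"""Muscle quantification: bias-field correction, Otsu fat/muscle split, CSA metrics.

The measurement chain mirrors how paraspinal muscle quality is quantified
on a single axial T2-weighted slice:

1. fit a quadratic polynomial intensity surface over the muscle ROIs and
   divide it out (MRI receive-coil inhomogeneity is well modelled as a
   smooth multiplicative field);
2. find the intensity threshold separating lean muscle (low signal) from
   fat/edema (high signal) by maximising Otsu's inter-class variance on
   the pooled bilateral ROI histogram;
3. classify ROI pixels into a binary fat/muscle map and count areas.

Areas: TCSA (total cross-sectional area of the bilateral paraspinal ROI),
FCSA (the muscle-class subset of TCSA).  Both are normalised by the L3
superior endplate CSA to remove body-size effects (RTCSA, RFCSA), and the
longitudinal endpoint is

    ΔRCSA = RFCSA_fu / RTCSA_fu − RFCSA_pre / RTCSA_pre,

the change in the functional fraction of the muscle from the preoperative
scan to follow-up; negative values mean loss of muscle quality.  Note that
the endplate normaliser cancels algebraically inside each fraction, so
ΔRCSA is exactly invariant to the endplate areas used at each timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import BiasFitError, DegenerateHistogramError
from .io import ENDPLATE, LEFT_MUSCLE, MUSCLE_LABELS, RIGHT_MUSCLE, ImageSlice, ROISet

__all__ = [
    "BiasField",
    "FatMuscleMap",
    "MuscleMetrics",
    "DeltaRCSA",
    "fit_bias_field",
    "correct_bias",
    "otsu_threshold",
    "classify_fat_muscle",
    "compute_tcsa",
    "compute_fcsa",
    "relative_metrics",
    "delta_rcsa",
    "average_raters",
]


def normalized_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (x̂, ŷ) grids spanning [-1, 1] across columns and rows."""
    nrow, ncol = shape
    y = np.linspace(-1.0, 1.0, nrow)[:, np.newaxis] * np.ones((1, ncol))
    x = np.linspace(-1.0, 1.0, ncol)[np.newaxis, :] * np.ones((nrow, 1))
    return x, y


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # columns: 1, x, y, x², xy, y²
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class BiasField:
    """Quadratic intensity surface b(x̂, ŷ) fitted over a region.

    ``coefficients`` are the raw least-squares coefficients
    (c00, c10, c01, c20, c11, c02); ``normalization`` is the mean of the
    raw surface over the fitted region, so the normalised surface
    ``coefficients / normalization`` has mean 1 there (dimensionless).
    """

    coefficients: np.ndarray
    normalization: float
    shape: tuple[int, int]
    region: np.ndarray = field(repr=False)

    def surface(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Evaluate the *normalised* (mean-1 over region) surface on a grid."""
        shape = shape or self.shape
        x, y = normalized_coords(shape)
        raw = _design_matrix(x.ravel(), y.ravel()) @ self.coefficients
        return raw.reshape(shape) / self.normalization


def fit_bias_field(
    sl: ImageSlice,
    roi: ROISet | None = None,
    *,
    whole_image: bool = False,
) -> BiasField:
    """Least-squares fit of the 6-coefficient quadratic surface.

    The surface is fitted to raw intensities over the union of the two
    muscle ROIs by default (the fat/muscle histogram lives inside the
    segmentations, so that is where the field must be flat after
    correction); ``whole_image=True`` fits over every pixel instead.
    """
    if whole_image or roi is None:
        region = np.ones(sl.shape, dtype=bool)
    else:
        region = roi.region(*MUSCLE_LABELS)
    npix = int(region.sum())
    if npix < 6:
        raise BiasFitError(f"region has {npix} pixels; at least 6 required for a quadratic fit")
    x, y = normalized_coords(sl.shape)
    design = _design_matrix(x[region], y[region])
    if np.linalg.matrix_rank(design) < 6:
        raise BiasFitError(
            "rank-deficient quadratic design over the region "
            "(e.g. all pixels on one row/column); cannot fit 6 coefficients"
        )
    coeffs, *_ = np.linalg.lstsq(design, sl.pixels[region], rcond=None)
    fitted = design @ coeffs
    norm = float(fitted.mean())
    if norm <= 0 or np.any(fitted / norm <= 0):
        raise BiasFitError(
            "fitted surface is non-positive over the region; "
            "a multiplicative correction is undefined"
        )
    return BiasField(coefficients=coeffs, normalization=norm, shape=sl.shape, region=region)


def correct_bias(sl: ImageSlice, bias: BiasField) -> ImageSlice:
    """Divide out the normalised bias surface.

    Corrected intensity = raw / surface, then rescaled so the mean
    intensity over the fitted region is exactly preserved (division by a
    mean-1 surface preserves the mean of a perfectly fitted image but not
    of an arbitrary one).  Pixels where the extrapolated surface is
    non-positive are an error if they lie inside the fitted region; outside
    it they are left uncorrected, since no downstream measurement uses
    them.
    """
    surf = bias.surface(sl.shape)
    if np.any(surf[bias.region] <= 0):
        raise BiasFitError("bias surface non-positive inside the fitted region")
    corrected = sl.pixels.copy()
    usable = surf > 0
    corrected[usable] = sl.pixels[usable] / surf[usable]
    raw_mean = sl.pixels[bias.region].mean()
    corr_mean = corrected[bias.region].mean()
    if corr_mean > 0:
        corrected[usable] *= raw_mean / corr_mean
    corrected = np.maximum(corrected, 0.0)
    return ImageSlice(
        pixels=corrected,
        spacing_row=sl.spacing_row,
        spacing_col=sl.spacing_col,
        patient_id=sl.patient_id,
        timepoint=sl.timepoint,
        level=sl.level,
    )


def otsu_threshold(intensities: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a pooled ROI intensity sample.

    Candidate thresholds are the interior edges of ``n_bins`` equal-width
    bins spanning [min, max] of the sample.  For each candidate t the
    sample is split into classes {≤ t} and {> t} and the inter-class
    variance ω0·ω1·(μ0−μ1)² is evaluated on the actual intensities; the
    returned threshold is the argmax, ties broken toward the lowest
    threshold.  Candidates leaving a class empty are skipped.
    """
    vals = np.asarray(intensities, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("empty intensity sample")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise DegenerateHistogramError(
            "degenerate histogram: all ROI intensities identical; no fat/muscle split exists"
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    candidates = edges[1:-1]
    svals = np.sort(vals)
    n = svals.size
    csum = np.concatenate([[0.0], np.cumsum(svals)])
    total = csum[-1]
    # split index per candidate: count of values <= t
    idx = np.searchsorted(svals, candidates, side="right")
    valid = (idx > 0) & (idx < n)
    if not np.any(valid):
        raise DegenerateHistogramError(
            "degenerate histogram: no candidate threshold separates two non-empty classes"
        )
    idx_v = idx[valid]
    w0 = idx_v / n
    mu0 = csum[idx_v] / idx_v
    mu1 = (total - csum[idx_v]) / (n - idx_v)
    bcv = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    best = int(np.argmax(bcv))  # argmax returns the first (lowest) maximiser
    return float(candidates[valid][best])


@dataclass
class FatMuscleMap:
    """Binary fat/muscle classification defined only on ROI pixels.

    ``muscle`` marks low-intensity (lean muscle) ROI pixels; ROI pixels not
    marked are the single high-intensity fat-or-edema class.  Pixels
    outside the ROI carry no class.
    """

    muscle: np.ndarray
    roi_mask: np.ndarray
    threshold: float

    @property
    def n_muscle(self) -> int:
        return int(self.muscle.sum())

    @property
    def n_fat(self) -> int:
        return int(self.roi_mask.sum() - self.muscle.sum())


def classify_fat_muscle(
    corrected: ImageSlice,
    roi: ROISet,
    threshold: float,
    labels: tuple[int, ...] = MUSCLE_LABELS,
) -> FatMuscleMap:
    """Split ROI pixels at the threshold: ≤ threshold muscle, > threshold fat."""
    region = roi.region(*labels)
    if not region.any():
        raise ValueError(f"empty ROI for labels {labels}")
    muscle = region & (corrected.pixels <= threshold)
    return FatMuscleMap(muscle=muscle, roi_mask=region, threshold=float(threshold))


_SIDE_LABELS = {
    "left": (LEFT_MUSCLE,),
    "right": (RIGHT_MUSCLE,),
    "bilateral": MUSCLE_LABELS,
}


def compute_tcsa(roi: ROISet, side: str, pixel_area: float) -> float:
    """Total CSA in mm²: labelled pixel count x pixel area (bilateral = L + R)."""
    try:
        labels = _SIDE_LABELS[side]
    except KeyError:
        raise ValueError(f"side must be one of {sorted(_SIDE_LABELS)}, got {side!r}") from None
    count = roi.pixel_count(*labels)
    if count == 0:
        raise ValueError(f"requested region {side!r} is empty")
    return count * pixel_area


def compute_fcsa(fat_map: FatMuscleMap, pixel_area: float) -> float:
    """Functional CSA in mm²: muscle-class pixel count x pixel area."""
    return fat_map.n_muscle * pixel_area


@dataclass
class MuscleMetrics:
    """Per patient/timepoint/rater areas and size-normalised ratios."""

    tcsa: float
    fcsa: float
    endplate_csa: float
    rtcsa: float
    rfcsa: float
    patient_id: str = ""
    timepoint: str = "pre"
    rater_id: str = "rater1"

    def __post_init__(self) -> None:
        if not (0 <= self.fcsa <= self.tcsa):
            raise ValueError(f"0 <= FCSA <= TCSA violated: fcsa={self.fcsa}, tcsa={self.tcsa}")
        if self.endplate_csa <= 0:
            raise ValueError(f"endplate CSA must be positive, got {self.endplate_csa}")


def relative_metrics(
    tcsa: float,
    fcsa: float,
    endplate_csa: float,
    *,
    patient_id: str = "",
    timepoint: str = "pre",
    rater_id: str = "rater1",
) -> MuscleMetrics:
    """Normalise areas by the L3 superior endplate CSA (RTCSA, RFCSA)."""
    if endplate_csa <= 0:
        raise ValueError(f"endplate CSA must be positive, got {endplate_csa}")
    return MuscleMetrics(
        tcsa=tcsa,
        fcsa=fcsa,
        endplate_csa=endplate_csa,
        rtcsa=tcsa / endplate_csa,
        rfcsa=fcsa / endplate_csa,
        patient_id=patient_id,
        timepoint=timepoint,
        rater_id=rater_id,
    )


def endplate_csa(roi: ROISet, pixel_area: float) -> float:
    """CSA of the L3 superior endplate label in mm²."""
    count = roi.pixel_count(ENDPLATE)
    if count == 0:
        raise ValueError("endplate label is empty")
    return count * pixel_area


@dataclass
class DeltaRCSA:
    """Change in the functional muscle fraction from pre-op to follow-up."""

    value: float
    pre_fraction: float
    fu_fraction: float
    patient_id: str = ""
    rater_id: str = "rater1"

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"ΔRCSA must lie in [-1, 1], got {self.value}")


def delta_rcsa(pre: MuscleMetrics, fu: MuscleMetrics) -> DeltaRCSA:
    """ΔRCSA = RFCSA_fu/RTCSA_fu − RFCSA_pre/RTCSA_pre for one rater.

    Negative values indicate a reduction in relative functional muscle
    area at follow-up.  The endplate normaliser cancels inside each
    fraction, so the result only depends on FCSA/TCSA at each timepoint.
    """
    if pre.patient_id != fu.patient_id:
        raise ValueError(f"timepoints from different patients: {pre.patient_id!r} vs {fu.patient_id!r}")
    if pre.rater_id != fu.rater_id:
        raise ValueError(f"timepoints from different raters: {pre.rater_id!r} vs {fu.rater_id!r}")
    if pre.rtcsa == 0 or fu.rtcsa == 0:
        raise ZeroDivisionError("RTCSA is zero at one timepoint; fraction undefined")
    # RFCSA/RTCSA == FCSA/TCSA exactly: computing the fraction from the raw
    # areas realises the algebraic cancellation of the endplate normaliser
    # bit-exactly instead of only up to floating-point rounding.
    pre_frac = pre.fcsa / pre.tcsa
    fu_frac = fu.fcsa / fu.tcsa
    return DeltaRCSA(
        value=fu_frac - pre_frac,
        pre_fraction=pre_frac,
        fu_fraction=fu_frac,
        patient_id=pre.patient_id,
        rater_id=pre.rater_id,
    )


def average_raters(r1: DeltaRCSA, r2: DeltaRCSA) -> DeltaRCSA:
    """Average-ΔRCSA: arithmetic mean of two independent raters' values."""
    if r1.patient_id != r2.patient_id:
        raise ValueError(f"different patients: {r1.patient_id!r} vs {r2.patient_id!r}")
    if r1.rater_id == r2.rater_id:
        raise ValueError(f"both measurements are from rater {r1.rater_id!r}; two raters required")
    return DeltaRCSA(
        value=0.5 * (r1.value + r2.value),
        pre_fraction=0.5 * (r1.pre_fraction + r2.pre_fraction),
        fu_fraction=0.5 * (r1.fu_fraction + r2.fu_fraction),
        patient_id=r1.patient_id,
        rater_id="average",
    )
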