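"""Reading and writing axial MRI slices and rater-drawn label masks.

Slices arrive as single-frame DICOM or as NIfTI-1 volumes (with a slice
index when 3-D); masks as NIfTI or 16-bit PNG label images.  Geometry is
validated on load: cross-sectional areas in mm² are only meaningful when
the in-plane pixel spacing is known, so missing spacing metadata is a hard
error rather than a silently assumed 1 mm default.

Label convention (configurable via ``label_map``):

====== =============================
 value  region
====== =============================
 0      background
 1      left paraspinal muscle
 2      right paraspinal muscle
 3      L3 superior vertebral endplate
====== =============================

Masks align to slices by exact grid shape; no resampling is performed, so
areas are always measured on the native image grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .exceptions import GeometryError, MaskLabelError, MissingMetadataError

BACKGROUND, LEFT_MUSCLE, RIGHT_MUSCLE, ENDPLATE = 0, 1, 2, 3
VALID_LABELS = frozenset({BACKGROUND, LEFT_MUSCLE, RIGHT_MUSCLE, ENDPLATE})
MUSCLE_LABELS = (LEFT_MUSCLE, RIGHT_MUSCLE)

TIMEPOINTS = ("pre", "followup")
LEVELS = ("L4L5", "L5S1")

MIN_GRID = 16


@dataclass
class ImageSlice:
    """One 2-D axial T2-weighted slice with physical pixel spacing.

    Intensities are in arbitrary scanner units.  ``degenerate`` is set when
    every pixel carries the same value (a constant image is tolerated but
    flagged: thresholding it is meaningless).
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    patient_id: str = ""
    timepoint: str = "pre"
    level: str | None = None
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise GeometryError(f"pixel grid must be 2-D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < MIN_GRID:
            raise GeometryError(
                f"pixel grid {self.pixels.shape} smaller than {MIN_GRID}x{MIN_GRID}"
            )
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise GeometryError(
                f"pixel spacing must be positive, got ({self.spacing_row}, {self.spacing_col})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS} or None, got {self.level!r}")
        self.degenerate = bool(self.pixels.max() == self.pixels.min())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ROISet:
    """Integer label mask aligned to one :class:`ImageSlice`.

    ``empty_labels`` lists muscle/endplate labels that are present in the
    convention but contain no pixels; loading carries this as a
    warning-level flag rather than an error so that single-region masks
    (e.g. endplate-only follow-up masks) remain usable.
    """

    mask: np.ndarray
    rater_id: str = "rater1"
    empty_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise GeometryError(f"mask must be 2-D, got ndim={self.mask.ndim}")
        if not np.issubdtype(self.mask.dtype, np.integer):
            if not np.all(self.mask == np.round(self.mask)):
                raise MaskLabelError("mask contains non-integer values")
            self.mask = self.mask.astype(np.int32)
        found = set(np.unique(self.mask).tolist())
        bad = sorted(found - VALID_LABELS)
        if bad:
            raise MaskLabelError(f"mask contains unknown label values {bad}; expected subset of {sorted(VALID_LABELS)}")
        if not self.rater_id:
            raise ValueError("rater_id must be a non-empty identifier")
        self.empty_labels = tuple(lab for lab in (LEFT_MUSCLE, RIGHT_MUSCLE, ENDPLATE) if lab not in found)

    def region(self, *labels: int) -> np.ndarray:
        """Boolean mask of the union of the given label values."""
        return np.isin(self.mask, labels)

    def pixel_count(self, *labels: int) -> int:
        return int(self.region(*labels).sum())


def roi_pixel_area(sl: ImageSlice) -> float:
    """Physical area of one pixel in mm² (spacing_row x spacing_col)."""
    return float(sl.spacing_row * sl.spacing_col)


# ---------------------------------------------------------------------------
# readers


def read_slice(
    path: str | Path,
    dialect: str,
    *,
    slice_index: int | None = None,
    patient_id: str | None = None,
    timepoint: str = "pre",
    level: str | None = None,
) -> ImageSlice:
    """Load a single axial slice from DICOM or NIfTI.

    Pixel spacing is taken from the file's metadata (DICOM ``PixelSpacing``;
    NIfTI in-plane zooms).  A 3-D NIfTI or multi-frame DICOM requires
    ``slice_index``; supplying none is an error that names the selector.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dicom":
        return _read_dicom(path, slice_index, patient_id, timepoint, level)
    if dialect == "nifti":
        return _read_nifti(path, slice_index, patient_id, timepoint, level)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'dicom' or 'nifti'")


def _read_dicom(path, slice_index, patient_id, timepoint, level) -> ImageSlice:
    ds = pydicom.dcmread(path)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise MissingMetadataError(
            f"{path}: DICOM dataset has no PixelSpacing; area in mm² would be undefined"
        )
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    pixels = ds.pixel_array
    if n_frames > 1:
        if slice_index is None:
            raise ValueError(
                f"{path}: multi-frame DICOM ({n_frames} frames) requires slice_index"
            )
        pixels = pixels[slice_index]
    return ImageSlice(
        pixels=pixels,
        spacing_row=float(spacing[0]),
        spacing_col=float(spacing[1]),
        patient_id=patient_id if patient_id is not None else str(getattr(ds, "PatientID", "")),
        timepoint=timepoint,
        level=level,
    )


def _read_nifti(path, slice_index, patient_id, timepoint, level) -> ImageSlice:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if len(zooms) < 2 or not (zooms[0] > 0 and zooms[1] > 0):
        raise MissingMetadataError(f"{path}: NIfTI header lacks positive in-plane voxel sizes")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] == 1:
            data = data[:, :, 0]
        elif slice_index is None:
            raise ValueError(
                f"{path}: 3-D NIfTI ({data.shape[2]} slices) requires slice_index"
            )
        else:
            data = data[:, :, slice_index]
    elif data.ndim != 2:
        raise GeometryError(f"{path}: expected 2-D or 3-D NIfTI, got ndim={data.ndim}")
    return ImageSlice(
        pixels=data,
        spacing_row=float(zooms[0]),
        spacing_col=float(zooms[1]),
        patient_id=patient_id or "",
        timepoint=timepoint,
        level=level,
    )


def read_mask(
    path: str | Path,
    sl: ImageSlice,
    *,
    rater_id: str = "rater1",
    label_map: dict[int, int] | None = None,
) -> ROISet:
    """Load a label mask (NIfTI or PNG) and validate it against a slice.

    ``label_map`` remaps file label values to the package convention before
    validation.  A shape mismatch with the paired slice is an error (masks
    are never resampled); empty muscle labels are warned about and flagged
    on the returned :class:`ROISet`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
    elif suffix.endswith(".png"):
        data = np.array(Image.open(path))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}; expected .nii(.gz) or .png")
    data = np.asarray(data)
    if data.shape != sl.shape:
        raise GeometryError(
            f"mask shape {data.shape} does not match slice shape {sl.shape}"
        )
    if label_map:
        remapped = np.zeros_like(data)
        for src, dst in label_map.items():
            remapped[data == src] = dst
        data = remapped
    roi = ROISet(mask=data, rater_id=rater_id)
    missing_muscle = [lab for lab in MUSCLE_LABELS if lab in roi.empty_labels]
    if missing_muscle:
        warnings.warn(
            f"{path}: muscle label(s) {missing_muscle} are empty", stacklevel=2
        )
    return roi


# ---------------------------------------------------------------------------
# writers (used by the synthetic fixture generator and the CLI)


def write_slice_nifti(sl: ImageSlice, path: str | Path) -> None:
    affine = np.diag([sl.spacing_row, sl.spacing_col, 1.0, 1.0])
    img = nib.Nifti1Image(sl.pixels[:, :, np.newaxis], affine)
    img.header.set_zooms((sl.spacing_row, sl.spacing_col, 1.0))
    nib.save(img, str(path))


def write_slice_dicom(sl: ImageSlice, path: str | Path) -> None:
    """Write as a single-frame secondary-capture DICOM (uint16 payload).

    Intensities must be non-negative integers representable in 16 bits;
    callers writing float phantoms should round first (DICOM round-trips
    are bit-exact only for integer-valued grids).
    """
    px = sl.pixels
    if np.any(px < 0) or np.any(px != np.round(px)) or px.max() > 65535:
        raise ValueError("DICOM writer requires integer intensities in [0, 65535]")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = sl.patient_id
    ds.Rows, ds.Columns = sl.shape
    ds.PixelSpacing = [sl.spacing_row, sl.spacing_col]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = px.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_mask_nifti(roi: ROISet, sl: ImageSlice, path: str | Path) -> None:
    affine = np.diag([sl.spacing_row, sl.spacing_col, 1.0, 1.0])
    img = nib.Nifti1Image(roi.mask.astype(np.int16)[:, :, np.newaxis], affine)
    nib.save(img, str(path))


def write_mask_png(roi: ROISet, path: str | Path) -> None:
    Image.fromarray(roi.mask.astype(np.uint16)).save(str(path))
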