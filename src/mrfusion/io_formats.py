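"""Image/mask/clinical-table I/O and patch assembly.

The pipeline operates on one axial slice per patient and per MRI sequence
(T2w, T1c, ADC), each carrying a binary tumor ROI mask drawn on the T2w
image and copied to the other sequences.  All geometry is handled at
1 mm x 1 mm pixel spacing: volumes/slices at other spacings are resampled
before feature extraction or patch cropping.

Conventions
-----------
* arrays are row-major, 0-based; patch windows are half-open ``[r0, r0+80)``
* channel order is fixed: ``("T2w", "T1c", "ADC")``
* masks are binarized at ``> 0`` on load
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

SEQUENCES = ("T2w", "T1c", "ADC")
PATCH_SIZE = 80

CLINICAL_COLUMNS = ["patient_id", "sex", "age", "cea", "cT", "cN", "response"]

_SEX = {"male": "male", "m": "male", "female": "female", "f": "female"}
_CEA = {"positive": "positive", "pos": "positive", "negative": "negative", "neg": "negative"}
_CT = {"T2", "T3", "T4"}
_CN = {"N0", "N1", "N2"}
_RESPONSE = {"poor": 1, "good": 0, "1": 1, "0": 0}


class AlignmentError(ValueError):
    """Image and mask grids (or heatmap and patch) do not align."""


class EmptyRoiError(ValueError):
    """The binary mask contains no foreground pixel."""


class MissingChannelError(KeyError):
    """A required MRI sequence is absent."""


class SchemaError(ValueError):
    """A table or feature registry does not match the expected schema."""


@dataclass
class AnnotatedSlice:
    """One 2D slice of one MRI sequence plus its binary ROI mask.

    ``spacing`` is (row_mm, col_mm); feature extraction requires (1.0, 1.0).
    """

    pixels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float]
    sequence_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.mask = np.asarray(self.mask) > 0
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.mask.shape != self.pixels.shape:
            raise AlignmentError(
                f"mask shape {self.mask.shape} != image shape {self.pixels.shape}"
            )
        if not self.mask.any():
            raise EmptyRoiError("ROI mask has no foreground pixel")
        if self.sequence_id not in SEQUENCES:
            raise ValueError(f"sequence_id must be one of {SEQUENCES}")
        r, c = self.spacing
        if not (r > 0 and c > 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.spacing = (float(r), float(c))

    @property
    def roi_values(self) -> np.ndarray:
        """In-mask intensities as a flat vector."""
        return self.pixels[self.mask]


@dataclass
class MultiSequencePatch:
    """3-channel 80x80 patch in (T2w, T1c, ADC) order for the CNN models."""

    channels: np.ndarray  # (3, 80, 80)
    label: int | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape != (3, PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch must be (3, {PATCH_SIZE}, {PATCH_SIZE}), got {self.channels.shape}"
            )


@dataclass
class ClinicalRecord:
    """Pre-treatment clinical covariates and the pathological response label.

    ``response`` is binary with 1 = poor responder (TRG 2/3) and
    0 = good responder (TRG 0/1).  CEA positivity uses the >= 5 ng/ml cutoff.
    """

    patient_id: str
    sex: str
    age: float
    cea: str
    cT: str
    cN: str
    response: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.cea not in ("positive", "negative"):
            raise ValueError(f"invalid cea {self.cea!r}")
        if self.cT not in _CT:
            raise ValueError(f"invalid cT {self.cT!r}")
        if self.cN not in _CN:
            raise ValueError(f"invalid cN {self.cN!r}")
        if self.response not in (0, 1):
            raise ValueError(f"invalid response {self.response!r}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")


# ---------------------------------------------------------------------------
# loading


def _read_grid(path: str | Path, mask_volume: np.ndarray | None = None):
    """Read a 2D grid (or reduce a 3D NIfTI volume to one slice).

    Returns ``(array2d, spacing_or_None, full_volume_or_None)``.  For a 3D
    NIfTI the slice with the largest mask area (axis 2) is selected; when no
    mask volume is supplied the caller selects the slice afterwards.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim == 2:
            return data, spacing, None
        if data.ndim == 3:
            return None, spacing, data
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # drop any color axis on PNG/TIFF
        arr = arr[..., 0]
    return arr, None, None


def load_annotated_slice(
    image_path: str | Path,
    mask_path: str | Path,
    sequence_id: str,
    spacing: tuple[float, float] | None = None,
) -> AnnotatedSlice:
    """Load an image + mask pair into an :class:`AnnotatedSlice`.

    NIfTI inputs take their spacing from the header; raw 2D formats
    (PNG/TIFF) use ``spacing`` or default to (1, 1) mm.  3D NIfTI volumes
    are reduced to the axial slice with the largest mask cross-section.
    Masks are binarized at > 0; an all-zero mask raises
    :class:`EmptyRoiError` and mismatched grids raise
    :class:`AlignmentError`.
    """
    img2d, hdr_spacing, img_vol = _read_grid(image_path)
    msk2d, _, msk_vol = _read_grid(mask_path)

    if img_vol is not None or msk_vol is not None:
        if img_vol is None or msk_vol is None or img_vol.shape != msk_vol.shape:
            a = img_vol.shape if img_vol is not None else img2d.shape
            b = msk_vol.shape if msk_vol is not None else msk2d.shape
            raise AlignmentError(f"image/mask volume shapes differ: {a} vs {b}")
        areas = (msk_vol > 0).sum(axis=(0, 1))
        if areas.max() == 0:
            raise EmptyRoiError("mask volume has no foreground voxel")
        k = int(areas.argmax())
        img2d, msk2d = img_vol[:, :, k], msk_vol[:, :, k]

    if img2d.shape != msk2d.shape:
        raise AlignmentError(f"image/mask shapes differ: {img2d.shape} vs {msk2d.shape}")
    use_spacing = hdr_spacing or spacing or (1.0, 1.0)
    return AnnotatedSlice(img2d, msk2d > 0, use_spacing, sequence_id)


# ---------------------------------------------------------------------------
# resampling


def resample_unit_spacing(sl: AnnotatedSlice) -> AnnotatedSlice:
    """Resample a slice to 1 mm x 1 mm pixel spacing.

    The image is interpolated bilinearly, the mask nearest-neighbour and
    re-binarized; the output grid is ``round(shape * spacing)``.  A slice
    already at unit spacing is returned unchanged.
    """
    if sl.spacing == (1.0, 1.0):
        return sl
    out_shape = (
        max(1, int(round(sl.pixels.shape[0] * sl.spacing[0]))),
        max(1, int(round(sl.pixels.shape[1] * sl.spacing[1]))),
    )
    zoom = (out_shape[0] / sl.pixels.shape[0], out_shape[1] / sl.pixels.shape[1])
    pixels = ndimage.zoom(sl.pixels, zoom, order=1, mode="nearest", grid_mode=True)
    mask = ndimage.zoom(sl.mask.astype(np.uint8), zoom, order=0, mode="nearest", grid_mode=True)
    # guard against rounding off-by-one from ndimage.zoom
    pixels = pixels[: out_shape[0], : out_shape[1]]
    mask = mask[: out_shape[0], : out_shape[1]]
    return AnnotatedSlice(pixels, mask > 0, (1.0, 1.0), sl.sequence_id)


# ---------------------------------------------------------------------------
# patch cropping


def zscore(arr: np.ndarray) -> np.ndarray:
    """Per-array z-score; constant arrays map to all zeros."""
    mu, sd = arr.mean(), arr.std()
    if sd == 0:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - mu) / sd


def crop_patch(
    slices: dict[str, AnnotatedSlice],
    label: int | None = None,
    patient_id: str = "",
    normalize: bool = True,
) -> MultiSequencePatch:
    """Cut one shared 80x80 window around the T2w ROI centroid.

    All three sequences are cropped with the same window (the ROI is drawn
    on T2w and copied across sequences, so one window is geometrically
    consistent).  Windows extending past the image border are zero padded.
    Each channel is then z-score normalized over the patch unless
    ``normalize=False``.
    """
    missing = [s for s in SEQUENCES if s not in slices]
    if missing:
        raise MissingChannelError(f"missing sequence(s): {missing}")
    for s in SEQUENCES:
        if slices[s].spacing != (1.0, 1.0):
            raise ValueError(f"sequence {s} not at unit spacing; resample first")

    ref = slices[SEQUENCES[0]]
    rows, cols = np.nonzero(ref.mask)
    r0 = int(round(rows.mean())) - PATCH_SIZE // 2
    c0 = int(round(cols.mean())) - PATCH_SIZE // 2

    channels = np.zeros((3, PATCH_SIZE, PATCH_SIZE), dtype=np.float64)
    for ci, s in enumerate(SEQUENCES):
        img = slices[s].pixels
        rs, re = max(r0, 0), min(r0 + PATCH_SIZE, img.shape[0])
        cs, ce = max(c0, 0), min(c0 + PATCH_SIZE, img.shape[1])
        if re > rs and ce > cs:
            channels[ci, rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
        if normalize:
            channels[ci] = zscore(channels[ci])
    return MultiSequencePatch(channels, label=label, patient_id=patient_id)


# ---------------------------------------------------------------------------
# clinical table


def read_clinical_table(csv_path: str | Path) -> list[ClinicalRecord]:
    """Read and validate the clinical covariate CSV.

    Expected header: ``patient_id,sex,age,cea,cT,cN,response``.  Category
    aliases (M/F, pos/neg, 0/1) are accepted; out-of-vocabulary values
    raise ``ValueError`` and missing columns raise :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(csv_path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty clinical table: {csv_path}") from exc
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s) {missing}")

    records = []
    for _, row in df.iterrows():
        sex = _SEX.get(str(row["sex"]).strip().lower())
        cea = _CEA.get(str(row["cea"]).strip().lower())
        resp = _RESPONSE.get(str(row["response"]).strip().lower())
        if sex is None:
            raise ValueError(f"invalid sex {row['sex']!r}")
        if cea is None:
            raise ValueError(f"invalid cea {row['cea']!r}")
        if resp is None:
            raise ValueError(f"invalid response {row['response']!r}")
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                sex=sex,
                age=float(row["age"]),
                cea=cea,
                cT=str(row["cT"]).strip(),
                cN=str(row["cN"]).strip(),
                response=resp,
            )
        )
    return records


def write_clinical_table(records: list[ClinicalRecord], csv_path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age": r.age,
                "cea": r.cea,
                "cT": r.cT,
                "cN": r.cN,
                "response": "poor" if r.response == 1 else "good",
            }
            for r in records
        ],
        columns=CLINICAL_COLUMNS,
    )
    df.to_csv(csv_path, index=False)


def save_slice_nifti(sl: AnnotatedSlice, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a slice and its mask as single-slice NIfTI files."""
    affine = np.diag([sl.spacing[0], sl.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(sl.pixels.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(sl.mask.astype(np.uint8), affine), str(mask_path))
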