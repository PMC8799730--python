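"""Containers and I/O for multi-slice grayscale volumes and binary masks.

Conventions
-----------
* Voxel grids are indexed ``(slice, row, col)``, 0-based.
* ``pixel_spacing`` is the in-plane ``(row_mm, col_mm)`` spacing;
  ``slice_positions`` are strictly increasing mm offsets along the
  through-plane axis.
* Polygon vertices follow the Labelme convention ``(x=col, y=row)``.

Supported formats: NIfTI (``.nii``/``.nii.gz``), PNG slice stacks
(``slice_0000.png`` ... in one directory) and read-only DICOM series.
When a format carries no spatial metadata (plain PNG stacks), spacing
falls back to the 0.7211 mm in-plane / 0.625 mm through-plane grid of a
fused T2-FLAIR head study, with a warning.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AlignmentError,
    FormatError,
    UnsupportedFormatError,
    ValidationError,
)

DEFAULT_PIXEL_SPACING: tuple[float, float] = (0.7211, 0.7211)
DEFAULT_SLICE_THICKNESS: float = 0.625

_PNG_NAME = "slice_{:04d}.png"
_PNG_META = "metadata.json"


@dataclass
class Volume:
    """A 3D scalar image grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Scalar intensities in arbitrary units.
    pixel_spacing : (float, float)
        In-plane (row_mm, col_mm) spacing, strictly positive.
    slice_positions : ndarray, shape (slices,)
        Strictly increasing mm offsets of each slice.
    meta : dict
        Free-form provenance tags.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float] = DEFAULT_PIXEL_SPACING
    slice_positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxels must be 3D (slice, row, col); got ndim={self.voxels.ndim}"
            )
        if self.slice_positions is None:
            self.slice_positions = (
                np.arange(self.voxels.shape[0], dtype=float) * DEFAULT_SLICE_THICKNESS
            )
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.voxels.shape[0],):
            raise ValidationError(
                "slice_positions length must equal the number of slices"
            )
        if self.voxels.shape[0] > 1 and not np.all(np.diff(self.slice_positions) > 0):
            raise ValidationError("slice_positions must be strictly increasing")
        ps = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if ps[0] <= 0 or ps[1] <= 0:
            raise ValidationError(f"pixel_spacing must be positive, got {ps}")
        self.pixel_spacing = ps

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_thickness(self) -> float:
        """Median spacing between consecutive slices (mm)."""
        if self.n_slices < 2:
            return DEFAULT_SLICE_THICKNESS
        return float(np.median(np.diff(self.slice_positions)))


@dataclass
class MaskVolume:
    """A {0,1} labeling aligned voxel-for-voxel to a :class:`Volume`."""

    labels: np.ndarray
    pixel_spacing: tuple[float, float] = DEFAULT_PIXEL_SPACING
    slice_positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be 3D (slice, row, col)")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask values must be in {{0,1}}; got {vals[:10]}")
        self.labels = self.labels.astype(np.uint8)
        if self.slice_positions is None:
            self.slice_positions = (
                np.arange(self.labels.shape[0], dtype=float) * DEFAULT_SLICE_THICKNESS
            )
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.labels.shape[0],):
            raise ValidationError(
                "slice_positions length must equal the number of slices"
            )
        ps = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if ps[0] <= 0 or ps[1] <= 0:
            raise ValidationError(f"pixel_spacing must be positive, got {ps}")
        self.pixel_spacing = ps

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_aligned(self, reference: "Volume | MaskVolume") -> None:
        ref_shape = reference.shape
        if self.shape != ref_shape:
            raise AlignmentError(
                f"mask shape {self.shape} does not match reference {ref_shape}"
            )


@dataclass
class PolygonAnnotation:
    """A closed polygon drawn on one slice, Labelme style.

    ``vertices`` are ordered ``(x, y)`` pixel coordinates with x along
    columns and y along rows; at least 3 points.
    """

    label: str
    slice_index: int
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError(
                f"polygon '{self.label}' needs >=3 vertices, got {len(self.vertices)}"
            )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _warn_default_spacing(path: Path) -> None:
    warnings.warn(
        f"{path}: no spatial metadata; assuming pixel spacing "
        f"{DEFAULT_PIXEL_SPACING} mm and slice thickness "
        f"{DEFAULT_SLICE_THICKNESS} mm",
        UserWarning,
        stacklevel=3,
    )


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI, got ndim={data.ndim}")
    # stored axis order is (x=col, y=row, z=slice); internal order is (z, y, x)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    pixel_spacing = (float(zooms[1]), float(zooms[0]))
    z0 = float(img.affine[2, 3])
    positions = z0 + np.arange(voxels.shape[0]) * float(zooms[2])
    return Volume(voxels, pixel_spacing, positions, meta={"source": str(path)})


def _write_nifti(voxels: np.ndarray, pixel_spacing, slice_positions, path: Path) -> None:
    import nibabel as nib

    diffs = np.diff(slice_positions)
    if len(diffs) and not np.allclose(diffs, diffs[0]):
        raise ValidationError(
            "NIfTI output requires uniformly spaced slices; "
            "resample (interpolate_slices) first"
        )
    dz = float(diffs[0]) if len(diffs) else DEFAULT_SLICE_THICKNESS
    affine = np.diag([pixel_spacing[1], pixel_spacing[0], dz, 1.0])
    affine[2, 3] = float(slice_positions[0])
    img = nib.Nifti1Image(np.ascontiguousarray(voxels.transpose(2, 1, 0)), affine)
    nib.save(img, str(path))


def _png_files(path: Path) -> list[Path]:
    files = sorted(p for p in path.iterdir() if re.fullmatch(r"slice_\d+\.png", p.name))
    if not files:
        raise IOError(f"no slice_*.png files found in {path}")
    return files


def _read_png_stack(path: Path) -> Volume:
    import imageio.v3 as iio

    if not path.is_dir():
        raise IOError(f"PNG stack path {path} is not a directory")
    slices = []
    for f in _png_files(path):
        try:
            arr = iio.imread(f)
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"cannot read PNG slice {f}: {exc}") from exc
        if arr.ndim == 3:  # collapse accidental RGB duplicates
            arr = arr[..., 0]
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"{path}: inconsistent slice shapes {sorted(shapes)}")
    voxels = np.stack(slices)
    meta_file = path / _PNG_META
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        spacing = tuple(meta["pixel_spacing"])
        positions = np.asarray(meta["slice_positions"], dtype=float)
    else:
        _warn_default_spacing(path)
        spacing = DEFAULT_PIXEL_SPACING
        positions = np.arange(voxels.shape[0]) * DEFAULT_SLICE_THICKNESS
    return Volume(voxels, spacing, positions, meta={"source": str(path)})


def _write_png_stack(voxels, pixel_spacing, slice_positions, path: Path) -> None:
    import imageio.v3 as iio

    if voxels.dtype.kind not in "iub":
        raise ValidationError(
            "PNG stacks store integer intensities; quantize the volume "
            "(e.g. round/scale to uint16) before writing"
        )
    if voxels.min() < 0 or voxels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("PNG stack intensities must fit in uint16 [0, 65535]")
    path.mkdir(parents=True, exist_ok=True)
    out = voxels.astype(np.uint16)
    for i in range(out.shape[0]):
        iio.imwrite(path / _PNG_NAME.format(i), out[i])
    (path / _PNG_META).write_text(
        json.dumps(
            {
                "pixel_spacing": list(pixel_spacing),
                "slice_positions": [float(p) for p in slice_positions],
            },
            sort_keys=True,
        )
    )


def _read_dicom_series(path: Path) -> Volume:
    import pydicom

    if not path.is_dir():
        raise IOError(f"DICOM series path {path} is not a directory")
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    if not files:
        raise IOError(f"no files found in DICOM series directory {path}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc

    def sort_key(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        if "SliceLocation" in ds:
            return float(ds.SliceLocation)
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise FormatError(f"{path}: DICOM series mixes slice shapes {sorted(shapes)}")
    voxels = np.stack([ds.pixel_array for ds in datasets])
    ds0 = datasets[0]
    if "PixelSpacing" in ds0:
        spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    else:
        _warn_default_spacing(path)
        spacing = DEFAULT_PIXEL_SPACING
    positions = np.array([sort_key(ds) for ds in datasets], dtype=float)
    if len(positions) > 1 and not np.all(np.diff(positions) > 0):
        dz = float(getattr(ds0, "SliceThickness", DEFAULT_SLICE_THICKNESS))
        positions = np.arange(len(datasets)) * dz
    return Volume(voxels, spacing, positions, meta={"source": str(path)})


def read_volume(path, format: str) -> Volume:
    """Read a grayscale volume from ``path``.

    ``format`` is one of ``nifti``, ``png_stack``, ``dicom_series``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume path does not exist: {path}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "png_stack":
        return _read_png_stack(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise UnsupportedFormatError(f"unknown volume format: {format!r}")


def write_volume(v: Volume, path, format: str) -> None:
    """Write ``v`` to ``path``; DICOM is read-only in this package."""
    path = Path(path)
    if format == "nifti":
        _write_nifti(v.voxels, v.pixel_spacing, v.slice_positions, path)
    elif format == "png_stack":
        _write_png_stack(v.voxels, v.pixel_spacing, v.slice_positions, path)
    elif format == "dicom_series":
        raise UnsupportedFormatError("writing DICOM series is not supported")
    else:
        raise UnsupportedFormatError(f"unknown volume format: {format!r}")


def read_mask(path, format: str, reference: Volume | None = None) -> MaskVolume:
    """Read a binary mask; any nonzero voxel becomes 1.

    If ``reference`` is given, the mask must match its shape exactly.
    """
    v = read_volume(path, format)
    mask = MaskVolume(
        (np.asarray(v.voxels) != 0).astype(np.uint8),
        v.pixel_spacing,
        v.slice_positions,
        meta=dict(v.meta),
    )
    if reference is not None:
        mask.check_aligned(reference)
    return mask


def write_mask(m: MaskVolume, path, format: str) -> None:
    """Write a mask; PNG stacks use {0, 255}, NIfTI uses {0, 1}."""
    if format == "png_stack":
        data = (m.labels * 255).astype(np.uint8)
    else:
        data = m.labels
    write_volume(
        Volume(data, m.pixel_spacing, m.slice_positions, meta=dict(m.meta)),
        path,
        format,
    )


# ---------------------------------------------------------------------------
# Polygon rasterization
# ---------------------------------------------------------------------------


def _fill_even_odd(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of one polygon on a pixel grid.

    A pixel (row r, col c) has its center at (x=c, y=r) and is inside iff
    a ray cast to +x from the center crosses the polygon boundary an odd
    number of times.  Edges are half-open in y, so a center exactly on a
    shared horizontal level is counted once; centers on a left edge are
    inside, on a right edge outside.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx.ravel().astype(float)
    y = yy.ravel().astype(float)
    inside = np.zeros(x.size, dtype=bool)
    v = np.asarray(vertices, dtype=float)
    nxt = np.roll(v, -1, axis=0)
    for (x0, y0), (x1, y1) in zip(v, nxt):
        if y0 == y1:  # horizontal edge never crosses the half-open scan level
            continue
        crosses = (y0 > y) != (y1 > y)
        with np.errstate(invalid="ignore"):
            x_at = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (x < x_at)
    return inside.reshape(shape)


def rasterize_polygons(
    annotations: list[PolygonAnnotation], reference: Volume
) -> MaskVolume:
    """Rasterize per-slice polygon annotations onto the grid of ``reference``.

    Multiple polygons on one slice are unioned; the fill rule is even-odd
    with pixel-center containment.
    """
    n_slices, rows, cols = reference.shape
    labels = np.zeros(reference.shape, dtype=np.uint8)
    for ann in annotations:
        if not isinstance(ann, PolygonAnnotation):
            ann = PolygonAnnotation(**ann)  # tolerate plain dicts
        if not 0 <= ann.slice_index < n_slices:
            raise ValidationError(
                f"annotation '{ann.label}' references slice {ann.slice_index} "
                f"outside volume with {n_slices} slices"
            )
        verts = np.asarray(ann.vertices, dtype=float)
        verts[:, 0] = np.clip(verts[:, 0], 0, cols - 1)
        verts[:, 1] = np.clip(verts[:, 1], 0, rows - 1)
        labels[ann.slice_index] |= _fill_even_odd(verts, (rows, cols)).astype(np.uint8)
    return MaskVolume(
        labels, reference.pixel_spacing, reference.slice_positions.copy()
    )


def load_labelme(path, slice_index: int = 0, label: str | None = None):
    """Parse a Labelme-style JSON file into :class:`PolygonAnnotation` objects.

    Expected structure: ``{"shapes": [{"label": ..., "points": [[x, y], ...]}]}``.
    The slice the file belongs to is not stored by Labelme, so the caller
    supplies ``slice_index`` (e.g. from a sidecar file-name -> index map).
    """
    data = json.loads(Path(path).read_text())
    out = []
    for shape in data.get("shapes", []):
        if label is not None and shape.get("label") != label:
            continue
        out.append(
            PolygonAnnotation(
                label=shape.get("label", "edema"),
                slice_index=slice_index,
                vertices=[tuple(p) for p in shape["points"]],
            )
        )
    return out
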