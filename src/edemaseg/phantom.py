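"""Synthetic T2-FLAIR-like head phantoms with known edema ground truth.

The phantom is deliberately piecewise-simple, in the tradition of
validation phantoms (Shepp-Logan and friends): an elliptical "head" of
brain tissue on a dark background, containing a single hyperintense
ellipsoidal edema lesion.  Tissue and background carry spatially
correlated Gaussian texture; the lesion interior is homogeneous by
default, as vasogenic edema appears on T2-FLAIR.  Two ground-truth masks
come with every volume:

* ``true_edema`` — the voxels inside the lesion ellipsoid (the intensity
  support of the lesion), and
* ``gts`` — a clinician-style delineation, which is ``true_edema``
  dilated in-plane by ``gts_margin_mm``.  Clinicians deliberately outline
  beyond the visible hyperintensity to cover possibly damaged tissue, so
  a faithful reference mask is *larger* than the intensity boundary.

With ``boundary_mode="diffuse"`` the lesion fades linearly into tissue
over ``diffuse_rim_mm``, emulating lesions whose boundary strength is
not obvious.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volumes_io import MaskVolume, Volume

# correlation length (pixels) of the in-plane noise texture
_TEXTURE_SIGMA_PX = 2.0


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic head volume.

    Attributes
    ----------
    shape : (slices, rows, cols)
    pixel_spacing : (row_mm, col_mm)
    slice_thickness : mm between consecutive slices
    head : ellipse semi-axes of the head as fractions of (rows, cols)
    background_mean, tissue_mean, edema_mean : intensities (a.u.);
        the lesion must be hyperintense (edema_mean > tissue_mean)
    noise_sd : per-tissue Gaussian texture sd, keys
        {"background", "tissue", "edema"}
    edema_center : lesion center in voxel coordinates (slice, row, col)
    edema_semi_axes_mm : ellipsoid semi-axes (slice_mm, row_mm, col_mm)
    boundary_mode : "sharp" or "diffuse"
    diffuse_rim_mm : width of the linear intensity ramp in diffuse mode
    gts_margin_mm : in-plane dilation of the clinician-style mask
    rng_seed : fully determines the generated bytes
    """

    shape: tuple[int, int, int] = (24, 96, 96)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0
    head: tuple[float, float] = (0.42, 0.36)
    background_mean: float = 10.0
    tissue_mean: float = 100.0
    edema_mean: float = 180.0
    noise_sd: dict = field(
        default_factory=lambda: {"background": 2.0, "tissue": 5.0, "edema": 0.0}
    )
    edema_center: tuple[int, int, int] = (12, 48, 48)
    edema_semi_axes_mm: tuple[float, float, float] = (6.0, 10.0, 8.0)
    boundary_mode: str = "sharp"
    diffuse_rim_mm: float = 3.0
    gts_margin_mm: float = 1.5
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.pixel_spacing) or self.slice_thickness <= 0:
            raise ValidationError("spacings must be strictly positive")
        if not (0 < self.head[0] <= 0.5 and 0 < self.head[1] <= 0.5):
            raise ValidationError("head semi-axes must be fractions in (0, 0.5]")
        if self.edema_mean <= self.tissue_mean:
            raise ValidationError(
                "edema must be hyperintense: edema_mean > tissue_mean"
            )
        if set(self.noise_sd) != {"background", "tissue", "edema"}:
            raise ValidationError(
                "noise_sd needs keys {'background','tissue','edema'}"
            )
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValidationError("noise sds must be >= 0")
        if any(a <= 0 for a in self.edema_semi_axes_mm):
            raise ValidationError("edema semi-axes must be positive")
        if self.boundary_mode not in ("sharp", "diffuse"):
            raise ValidationError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.diffuse_rim_mm <= 0:
            raise ValidationError("diffuse_rim_mm must be positive")
        if self.gts_margin_mm < 0:
            raise ValidationError("gts_margin_mm must be >= 0")


def default_clinical_spec() -> PhantomSpec:
    """Spec matching a fused T2-FLAIR head study grid.

    512x512 in-plane at 0.7211 mm pixel spacing, 0.625 mm slice thickness,
    109 slices, with a lesion spanning several tens of slices.
    """
    return PhantomSpec(
        shape=(109, 512, 512),
        pixel_spacing=(0.7211, 0.7211),
        slice_thickness=0.625,
        head=(0.42, 0.36),
        background_mean=10.0,
        tissue_mean=100.0,
        edema_mean=180.0,
        noise_sd={"background": 2.0, "tissue": 5.0, "edema": 0.0},
        edema_center=(54, 256, 300),
        edema_semi_axes_mm=(15.0, 18.0, 14.0),
        boundary_mode="sharp",
        diffuse_rim_mm=3.0,
        gts_margin_mm=1.5,
        rng_seed=0,
    )


def _head_mask(spec: PhantomSpec) -> np.ndarray:
    _, rows, cols = spec.shape
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    ar, ac = spec.head[0] * rows, spec.head[1] * cols
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((yy - rc) / ar) ** 2 + ((xx - cc) / ac) ** 2 <= 1.0


def _edema_distance(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoid distance d; the lesion is d <= 1."""
    s, r, c = spec.shape
    cs, cr, cc = spec.edema_center
    a_s, a_r, a_c = spec.edema_semi_axes_mm
    zz = (np.arange(s) - cs)[:, None, None] * spec.slice_thickness / a_s
    yy = (np.arange(r) - cr)[None, :, None] * spec.pixel_spacing[0] / a_r
    xx = (np.arange(c) - cc)[None, None, :] * spec.pixel_spacing[1] / a_c
    return np.sqrt(zz**2 + yy**2 + xx**2)


def _disc(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, MaskVolume, MaskVolume]:
    """Generate ``(volume, true_edema, gts)`` from ``spec``.

    Deterministic: identical spec (including ``rng_seed``) yields
    byte-identical output.
    """
    spec.validate()
    head2d = _head_mask(spec)
    d = _edema_distance(spec).astype(np.float32)
    true_edema = d <= 1.0
    if not true_edema.any():
        raise ValidationError("edema ellipsoid contains no voxels on this grid")
    head3d = np.broadcast_to(head2d, spec.shape)
    if np.any(true_edema & ~head3d):
        raise ValidationError("edema region extends outside the head ellipse")

    base = np.full(spec.shape, spec.background_mean, dtype=np.float32)
    base[head3d] = spec.tissue_mean
    if spec.boundary_mode == "sharp":
        base[true_edema] = spec.edema_mean
    else:
        # linear ramp from edema_mean (d<=1) to tissue_mean over the rim;
        # rim width in mm is measured along the mean semi-axis direction
        rim = spec.diffuse_rim_mm / float(np.mean(spec.edema_semi_axes_mm))
        ramp = np.clip((1.0 + rim - d) / rim, 0.0, 1.0)
        lesion = ramp > 0
        base[lesion] = (
            spec.tissue_mean
            + (spec.edema_mean - spec.tissue_mean) * ramp[lesion]
        )
        base[true_edema] = spec.edema_mean

    rng = np.random.default_rng(spec.rng_seed)
    white = rng.standard_normal(spec.shape).astype(np.float32)
    texture = ndimage.gaussian_filter(
        white, sigma=(0.0, _TEXTURE_SIGMA_PX, _TEXTURE_SIGMA_PX)
    )
    texture /= max(float(texture.std()), np.finfo(np.float32).tiny)
    sd_map = np.full(spec.shape, spec.noise_sd["background"], dtype=np.float32)
    sd_map[head3d] = spec.noise_sd["tissue"]
    sd_map[true_edema] = spec.noise_sd["edema"]
    voxels = base + texture * sd_map

    positions = np.arange(spec.shape[0], dtype=float) * spec.slice_thickness
    meta = {"generator": "edemaseg.phantom", "rng_seed": spec.rng_seed}
    vol = Volume(voxels, spec.pixel_spacing, positions, meta=dict(meta))

    truth = MaskVolume(
        true_edema.astype(np.uint8), spec.pixel_spacing, positions.copy(),
        meta=dict(meta),
    )
    if spec.gts_margin_mm > 0:
        radius = spec.gts_margin_mm / float(np.mean(spec.pixel_spacing))
        foot = _disc(radius)[None, :, :]
        gts_labels = ndimage.binary_dilation(true_edema, structure=foot)
    else:
        gts_labels = true_edema
    gts = MaskVolume(
        gts_labels.astype(np.uint8), spec.pixel_spacing, positions.copy(),
        meta=dict(meta),
    )
    return vol, truth, gts


def spec_with(spec: PhantomSpec, **overrides) -> PhantomSpec:
    """Copy ``spec`` with fields replaced (convenience for configs)."""
    return replace(spec, **overrides)
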