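"""Data preparation: through-plane interpolation, normalization, paired
image-mask augmentation and dataset splitting.

Through-plane interpolation mirrors the clinical workflow in which a
coarse follow-up series (e.g. 5.0 mm T2-FLAIR) is resampled onto a fine
grid (e.g. 0.625 mm) before delineation: each output slice is the
position-weighted linear blend of the two bracketing acquired slices;
the in-plane grid is untouched.

Augmentation expands a small set of (slice, mask) pairs into a fixed-size
pool with geometric and intensity perturbations, applying geometric ops
identically to image and mask (nearest-neighbor for masks, so they stay
binary) and intensity ops to the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volumes_io import Volume

_ALL_OPS = ("hflip", "vflip", "rotate", "translate", "zoom", "intensity_scale")


# ---------------------------------------------------------------------------
# Through-plane interpolation
# ---------------------------------------------------------------------------


def interpolate_slices(v: Volume, new_thickness_mm: float) -> Volume:
    """Resample ``v`` onto a uniform through-plane grid.

    Output positions are ``first + k * new_thickness_mm`` for
    ``k = 0 .. floor(span / new_thickness_mm)``.  Positions that coincide
    with an acquired slice reproduce it exactly.
    """
    if v.n_slices < 2:
        raise ValidationError("interpolation needs at least 2 slices")
    if new_thickness_mm <= 0:
        raise ValidationError("new_thickness_mm must be positive")
    pos = v.slice_positions
    span = float(pos[-1] - pos[0])
    if new_thickness_mm > span:
        raise ValidationError(
            f"new thickness {new_thickness_mm} mm exceeds the volume span {span} mm"
        )
    n_out = int(np.floor(span / new_thickness_mm + 1e-9)) + 1
    new_pos = pos[0] + np.arange(n_out) * float(new_thickness_mm)
    new_pos[-1] = min(new_pos[-1], pos[-1])  # guard float overshoot

    idx_hi = np.searchsorted(pos, new_pos, side="left")
    idx_hi = np.clip(idx_hi, 1, v.n_slices - 1)
    idx_lo = idx_hi - 1
    w = (new_pos - pos[idx_lo]) / (pos[idx_hi] - pos[idx_lo])
    # snap to exact copies where the grid lands on an acquired slice
    w = np.where(np.abs(new_pos - pos[idx_lo]) < 1e-9, 0.0, w)
    w = np.where(np.abs(new_pos - pos[idx_hi]) < 1e-9, 1.0, w)

    vox = np.asarray(v.voxels)
    out = np.empty((n_out,) + vox.shape[1:], dtype=np.result_type(vox.dtype, float))
    for k in range(n_out):
        if w[k] == 0.0:
            out[k] = vox[idx_lo[k]]
        elif w[k] == 1.0:
            out[k] = vox[idx_hi[k]]
        else:
            out[k] = (1.0 - w[k]) * vox[idx_lo[k]] + w[k] * vox[idx_hi[k]]
    meta = dict(v.meta)
    meta["interpolated_from_thickness"] = v.slice_thickness()
    return Volume(out, v.pixel_spacing, new_pos, meta=meta)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------


def normalize_intensity(v: Volume, method: str = "minmax") -> Volume:
    """Rescale intensities: ``minmax`` to [0,1], ``zscore`` to mean 0 / sd 1.

    A constant volume maps to all zeros under ``minmax`` and is an error
    under ``zscore``.
    """
    vox = np.asarray(v.voxels, dtype=float)
    if method == "minmax":
        lo, hi = float(vox.min()), float(vox.max())
        out = np.zeros_like(vox) if hi == lo else (vox - lo) / (hi - lo)
    elif method == "zscore":
        sd = float(vox.std())
        if sd == 0:
            raise ValidationError("zscore normalization undefined for a constant volume")
        out = (vox - float(vox.mean())) / sd
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return Volume(out, v.pixel_spacing, v.slice_positions.copy(), meta=dict(v.meta))


# ---------------------------------------------------------------------------
# Paired augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentSpec:
    """Augmentation recipe and pool accounting.

    ``pool_target`` pairs are produced (originals first, then randomly
    parameterized transforms of cyclically chosen originals);
    ``model_building_count`` of them are sampled without replacement for
    model building, the rest are held out for testing.  The defaults
    expand a 109-slice delineated series into an 800-pair pool split
    700 / 100.
    """

    ops: tuple = _ALL_OPS
    rotate_max_deg: float = 15.0
    translate_max_px: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    intensity_range: tuple[float, float] = (0.9, 1.1)
    pool_target: int = 800
    model_building_count: int = 700
    rng_seed: int = 0

    def validate(self) -> None:
        unknown = set(self.ops) - set(_ALL_OPS)
        if unknown:
            raise ValidationError(f"unknown augmentation ops: {sorted(unknown)}")
        if self.model_building_count > self.pool_target:
            raise ValidationError("model_building_count must be <= pool_target")
        if self.zoom_range[0] <= 0 or self.zoom_range[0] > self.zoom_range[1]:
            raise ValidationError(f"bad zoom_range {self.zoom_range}")
        if self.intensity_range[0] <= 0 or self.intensity_range[0] > self.intensity_range[1]:
            raise ValidationError(f"bad intensity_range {self.intensity_range}")


@dataclass
class SplitSpec:
    """Train/validation partition of the model-building set."""

    train_fraction: float = 0.8
    val_fraction: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.train_fraction <= 1 and 0 <= self.val_fraction <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(self.train_fraction + self.val_fraction - 1.0) > 1e-9:
            raise ValidationError("train_fraction + val_fraction must equal 1")


def _transform_pair(img, mask, spec: AugmentSpec, rng: np.random.Generator):
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if "hflip" in spec.ops and rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if "vflip" in spec.ops and rng.random() < 0.5:
        img, mask = img[::-1, :], mask[::-1, :]

    angle = rng.uniform(-spec.rotate_max_deg, spec.rotate_max_deg) if "rotate" in spec.ops else 0.0
    zoom = rng.uniform(*spec.zoom_range) if "zoom" in spec.ops else 1.0
    if "translate" in spec.ops:
        shift = rng.uniform(-spec.translate_max_px, spec.translate_max_px, size=2)
    else:
        shift = np.zeros(2)

    if angle != 0.0 or zoom != 1.0 or shift.any():
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        # output->input mapping about the frame center, out-of-frame filled with 0
        matrix = rot.T / zoom
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - matrix @ (center + shift)
        img = ndimage.affine_transform(img, matrix, offset=offset, order=1, cval=0.0)
        mask = ndimage.affine_transform(
            mask.astype(np.uint8), matrix, offset=offset, order=0, cval=0
        )

    if "intensity_scale" in spec.ops:
        img = img * rng.uniform(*spec.intensity_range)
    return np.ascontiguousarray(img), np.ascontiguousarray(mask.astype(np.uint8))


def augment_dataset(pairs, spec: AugmentSpec = AugmentSpec()):
    """Expand ``pairs`` of 2D (image, mask) into a pool and split off a
    model-building subset.

    Returns ``(pool, model_building, held_out)``; membership and transform
    parameters are fully determined by ``spec.rng_seed``.
    """
    spec.validate()
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("augment_dataset needs at least one input pair")
    if spec.pool_target < len(pairs):
        raise ValidationError(
            f"pool_target {spec.pool_target} < number of input pairs {len(pairs)}"
        )
    for img, mask in pairs:
        if np.asarray(img).shape != np.asarray(mask).shape:
            raise ValidationError("each image and its mask must share one shape")

    rng = np.random.default_rng(spec.rng_seed)
    pool = [
        (np.asarray(img, dtype=float), np.asarray(mask, dtype=np.uint8))
        for img, mask in pairs
    ]
    i = 0
    while len(pool) < spec.pool_target:
        img, mask = pairs[i % len(pairs)]
        pool.append(_transform_pair(img, mask, spec, rng))
        i += 1

    chosen = rng.choice(spec.pool_target, size=spec.model_building_count, replace=False)
    chosen_set = set(int(c) for c in chosen)
    model_building = [pool[j] for j in sorted(chosen_set)]
    held_out = [pool[j] for j in range(spec.pool_target) if j not in chosen_set]
    return pool, model_building, held_out


def split_dataset(model_building, spec: SplitSpec = SplitSpec()):
    """Partition into (train, val) with |train| = round-half-up(0.8 n)."""
    spec.validate()
    items = list(model_building)
    if not items:
        raise ValidationError("split_dataset needs a nonempty input")
    n = len(items)
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    rng = np.random.default_rng(spec.rng_seed)
    order = rng.permutation(n)
    train = [items[j] for j in order[:n_train]]
    val = [items[j] for j in order[n_train:]]
    return train, val
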