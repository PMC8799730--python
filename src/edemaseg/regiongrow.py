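"""Per-slice seeded region growing under a dynamic range-fraction criterion.

The acceptance rule: a candidate pixel P adjacent to the region R is
admitted iff

    |I(P) - I(S)| <= max(f * (max(R) - min(R)), tau0)

where S is the seed pixel, f defaults to 0.20, and max(R)/min(R) are the
extrema over the currently accepted pixels.  Because the extrema evolve
as R grows, the rule by itself is order-ambiguous; this implementation
computes the *fixed point*: a pixel belongs to the result iff the rule
admits it given the final accepted set reachable through admitted
neighbors.  The acceptance operator is monotone (more accepted pixels
can only raise the threshold), so the fixed point is unique and
independent of traversal order.  It is computed by synchronous frontier
sweeps: every round, all frame pixels adjacent to R that satisfy the
current threshold are admitted at once, the running extrema are updated,
and sweeping repeats until no frontier pixel qualifies — which also
re-examines pixels rejected earlier under a smaller threshold.

The region is initialized to the (clipped) ``init_window`` neighborhood
of the seed, accepted unconditionally: with R = {seed} alone the range is
zero and nothing but exact-equality pixels could ever be admitted, so a
non-degenerate initial range is implied by the procedure.  ``range_floor``
(tau0) provides an absolute threshold floor for seeds whose neighborhood
is uniform.

Growing is strictly 2D per slice; a volume segmentation is the stack of
independently grown slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volumes_io import MaskVolume, Volume

_STRUCT = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class Seed:
    """A 0-based (slice, row, col) starting pixel for region growing."""

    slice_index: int
    row: int
    col: int


@dataclass(frozen=True)
class GrowCriterion:
    """Parameters of the acceptance rule.

    fraction : f in (0, 1], default 0.20 — the fraction of the region's
        intensity range a candidate may deviate from the seed.
    connectivity : 4 or 8 in-plane neighbors (default 8).
    init_window : odd side length of the unconditionally accepted seed
        neighborhood (default 3).
    range_floor : tau0 >= 0, absolute lower bound on the threshold
        (default 0; useful when the seed neighborhood is uniform).
    mode : "dynamic" re-evaluates max(R) - min(R) as the region grows;
        "fixed" freezes the threshold at the initial neighborhood's range.
    """

    fraction: float = 0.20
    connectivity: int = 8
    init_window: int = 3
    range_floor: float = 0.0
    mode: str = "dynamic"

    def validate(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValidationError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.init_window < 1 or self.init_window % 2 == 0:
            raise ValidationError("init_window must be an odd integer >= 1")
        if self.range_floor < 0:
            raise ValidationError("range_floor must be >= 0")
        if self.mode not in ("dynamic", "fixed"):
            raise ValidationError(f"mode must be 'dynamic' or 'fixed', got {self.mode!r}")


@dataclass
class GrowResult:
    """Outcome of growing one seed on one slice."""

    mask: np.ndarray  # 2D uint8
    accepted_count: int
    final_range: float  # max(R) - min(R) over the final region
    iterations: int  # number of frontier sweeps


def _check_seed_bounds(img: np.ndarray, seed: Seed) -> None:
    rows, cols = img.shape
    if not (0 <= seed.row < rows and 0 <= seed.col < cols):
        raise ValidationError(
            f"seed (row={seed.row}, col={seed.col}) outside {rows}x{cols} slice"
        )


def grow_region(slice_img, seed: Seed, c: GrowCriterion = GrowCriterion()) -> GrowResult:
    """Grow one seed on one 2D slice; see the module docstring for semantics."""
    c.validate()
    img = np.asarray(slice_img, dtype=float)
    if img.ndim != 2:
        raise ValidationError(f"slice must be 2D, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise ValidationError("slice contains non-finite pixel values")
    _check_seed_bounds(img, seed)

    half = c.init_window // 2
    accepted = np.zeros(img.shape, dtype=bool)
    r0 = max(0, seed.row - half)
    r1 = min(img.shape[0], seed.row + half + 1)
    c0 = max(0, seed.col - half)
    c1 = min(img.shape[1], seed.col + half + 1)
    accepted[r0:r1, c0:c1] = True

    s_val = float(img[seed.row, seed.col])
    init_vals = img[accepted]
    mn, mx = float(init_vals.min()), float(init_vals.max())
    struct = _STRUCT[c.connectivity]
    dev = np.abs(img - s_val)

    def threshold(lo: float, hi: float) -> float:
        return max(c.fraction * (hi - lo), c.range_floor)

    t = threshold(mn, mx)
    iterations = 0
    while True:
        frontier = ndimage.binary_dilation(accepted, structure=struct) & ~accepted
        new = frontier & (dev <= t)
        if not new.any():
            break
        accepted |= new
        iterations += 1
        if c.mode == "dynamic":
            new_vals = img[new]
            lo, hi = float(new_vals.min()), float(new_vals.max())
            if lo < mn or hi > mx:
                mn, mx = min(mn, lo), max(mx, hi)
                t = threshold(mn, mx)

    return GrowResult(
        mask=accepted.astype(np.uint8),
        accepted_count=int(accepted.sum()),
        final_range=float(mx - mn),
        iterations=iterations,
    )


def grow_multi(slice_img, seeds, c: GrowCriterion = GrowCriterion()) -> np.ndarray:
    """Union of independently grown seeds on one slice (fail-fast on bounds)."""
    seeds = list(seeds)
    if not seeds:
        raise ValidationError("grow_multi needs at least one seed")
    img = np.asarray(slice_img, dtype=float)
    for s in seeds:
        _check_seed_bounds(img, s)
    mask = np.zeros(img.shape, dtype=np.uint8)
    for s in seeds:
        mask |= grow_region(img, s, c).mask
    return mask


def segment_volume(
    v: Volume, seeds_by_slice: dict, c: GrowCriterion = GrowCriterion()
) -> MaskVolume:
    """Grow every seeded slice of ``v``; unseeded slices stay empty."""
    labels = np.zeros(v.shape, dtype=np.uint8)
    for slice_index, seeds in seeds_by_slice.items():
        if not 0 <= int(slice_index) < v.n_slices:
            raise ValidationError(
                f"seed list references slice {slice_index} outside "
                f"volume with {v.n_slices} slices"
            )
    for slice_index, seeds in sorted(seeds_by_slice.items()):
        labels[int(slice_index)] = grow_multi(v.voxels[int(slice_index)], seeds, c)
    return MaskVolume(labels, v.pixel_spacing, v.slice_positions.copy())


def seeds_from_mask(mask: MaskVolume, min_area_px: int = 9) -> dict:
    """One centroid seed per slice of ``mask`` whose area is >= ``min_area_px``.

    Emulates an operator clicking the lesion core on each delineated
    slice.  Slices smaller than the growing init window cannot anchor a
    meaningful neighborhood range, so they are skipped by default.
    If the (rounded) centroid falls outside the mask, the nearest mask
    pixel is used instead.
    """
    out: dict[int, list[Seed]] = {}
    for k in range(mask.shape[0]):
        sl = mask.labels[k]
        area = int(sl.sum())
        if area < min_area_px:
            continue
        rr, cc = np.nonzero(sl)
        r = int(round(float(rr.mean())))
        c_ = int(round(float(cc.mean())))
        if not sl[r, c_]:
            j = int(np.argmin((rr - r) ** 2 + (cc - c_) ** 2))
            r, c_ = int(rr[j]), int(cc[j])
        out[k] = [Seed(k, r, c_)]
    return out
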