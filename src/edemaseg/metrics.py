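"""Volumetric overlap indices (DICE, IoU, VOE) and comparison reports.

For a predicted region R and a reference delineation GTS:

    DICE = 2|R ∩ GTS| / (|R| + |GTS|)
    IoU  = |R ∩ GTS| / |R ∪ GTS|          (Jaccard)
    VOE  = 1 − IoU                          (volumetric overlap error)

All three are mutually consistent for a single mask pair:
``dice = 2*iou / (1 + iou)`` and ``voe = 1 - iou``.  A pair of empty
masks scores (1, 1, 0): agreed absence is perfect agreement (the ratios
are otherwise 0/0 there).  VOE is stored as a fraction in [0, 1] and can
be rendered as a percentage at the reporting layer.

Aggregation is reported two ways, since both are common: pooled-voxel
*volumetric* scores over the whole stack, and the arithmetic *slice mean*
of per-slice scores over slices where R ∪ GTS is nonempty.  Note the
dice/iou identity holds per pair, not for independently averaged means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .volumes_io import MaskVolume


@dataclass(frozen=True)
class OverlapScores:
    """DICE / IoU / VOE for one mask pair (or an aggregate of pairs)."""

    dice: float
    iou: float
    voe_fraction: float

    @property
    def voe_percent(self) -> float:
        return 100.0 * self.voe_fraction

    @classmethod
    def from_counts(cls, inter: int, n_r: int, n_gts: int) -> "OverlapScores":
        union = n_r + n_gts - inter
        if union == 0:  # both masks empty: agreed absence
            return cls(1.0, 1.0, 0.0)
        iou = inter / union
        return cls(2.0 * inter / (n_r + n_gts), iou, 1.0 - iou)


@dataclass
class OverlapReport:
    """Per-slice and aggregated overlap scores for one mask pair."""

    per_slice: list  # [(slice_index, OverlapScores), ...] for every slice
    volumetric: OverlapScores  # pooled voxel counts over the whole stack
    slice_mean: OverlapScores  # mean over slices with nonempty union


def _as_bool_pair(r, gts):
    a = np.asarray(r.labels if isinstance(r, MaskVolume) else r).astype(bool)
    b = np.asarray(gts.labels if isinstance(gts, MaskVolume) else gts).astype(bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _scores(a: np.ndarray, b: np.ndarray) -> OverlapScores:
    return OverlapScores.from_counts(
        int(np.count_nonzero(a & b)), int(np.count_nonzero(a)), int(np.count_nonzero(b))
    )


def dice(r, gts) -> float:
    """2|R∩GTS| / (|R|+|GTS|); 1.0 when both masks are empty."""
    return _scores(*_as_bool_pair(r, gts)).dice


def iou(r, gts) -> float:
    """|R∩GTS| / |R∪GTS| (Jaccard); 1.0 when both masks are empty."""
    return _scores(*_as_bool_pair(r, gts)).iou


def voe(r, gts) -> float:
    """1 − IoU as a fraction; 0.0 when both masks are empty."""
    return _scores(*_as_bool_pair(r, gts)).voe_fraction


def overlap_scores(r, gts) -> OverlapScores:
    """All three indices for one mask pair."""
    return _scores(*_as_bool_pair(r, gts))


def evaluate(r: MaskVolume, gts: MaskVolume) -> OverlapReport:
    """Score ``r`` against ``gts`` per slice and volumetrically.

    The slice mean averages per-slice scores over slices where at least
    one mask is nonempty; if every slice is empty in both masks, the
    aggregate is the agreed-absence score (1, 1, 0).
    """
    a, b = _as_bool_pair(r, gts)
    if a.ndim != 3:
        raise ValidationError("evaluate expects 3D mask volumes")
    per_slice = []
    kept = []
    for k in range(a.shape[0]):
        s = _scores(a[k], b[k])
        per_slice.append((k, s))
        if a[k].any() or b[k].any():
            kept.append(s)
    if kept:
        slice_mean = OverlapScores(
            float(np.mean([s.dice for s in kept])),
            float(np.mean([s.iou for s in kept])),
            float(np.mean([s.voe_fraction for s in kept])),
        )
    else:
        slice_mean = OverlapScores(1.0, 1.0, 0.0)
    return OverlapReport(per_slice, _scores(a, b), slice_mean)


def report_frame(name: str, report: OverlapReport, percent: bool = False) -> pd.DataFrame:
    """Long-format frame: one row per slice plus VOLUME and SLICE_MEAN rows."""
    scale = 100.0 if percent else 1.0
    rows = [
        {
            "method": name,
            "slice_index": str(k),
            "dice": s.dice,
            "iou": s.iou,
            "voe": s.voe_fraction * scale,
        }
        for k, s in report.per_slice
    ]
    for tag, s in (("VOLUME", report.volumetric), ("SLICE_MEAN", report.slice_mean)):
        rows.append(
            {
                "method": name,
                "slice_index": tag,
                "dice": s.dice,
                "iou": s.iou,
                "voe": s.voe_fraction * scale,
            }
        )
    return pd.DataFrame(rows, columns=["method", "slice_index", "dice", "iou", "voe"])


def compare_methods(named_reports: dict) -> pd.DataFrame:
    """One summary row per method, ranked by volumetric DICE (descending,
    ties broken alphabetically); VOE rendered as percent."""
    if not named_reports:
        raise ValidationError("compare_methods needs at least one report")
    rows = []
    for name, rep in named_reports.items():
        rows.append(
            {
                "method": name,
                "dice_volume": rep.volumetric.dice,
                "iou_volume": rep.volumetric.iou,
                "voe_volume_percent": rep.volumetric.voe_percent,
                "dice_slice_mean": rep.slice_mean.dice,
                "iou_slice_mean": rep.slice_mean.iou,
                "voe_slice_mean_percent": rep.slice_mean.voe_percent,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["dice_volume", "method"], ascending=[False, True]
    ).reset_index(drop=True)
    return frame
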