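"""FROC analysis of detection proposals against ground-truth lesion masks.

Ground-truth lesions are the 26-connected components of the annotation
mask. A proposal counts as a true positive when its voxel IoU with some
still-unmatched lesion strictly exceeds 0.2; matching is greedy in
descending confidence order, each proposal consuming at most one lesion
(the highest-IoU candidate), so one detection can never validate two
lesions nor one lesion validate two detections.

The free-response ROC sweeps the confidence threshold over every proposal
score, giving (mean false positives per scan, lesion sensitivity) pairs.
Sensitivity is reported at 1/2, 1, 2, 4 and 8 FPs/scan — at each rate the
best sensitivity among thresholds whose FP load does not exceed the rate —
together with the arithmetic mean of the five.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .inference import DetectionProposal
from .volume import BinaryMask3D

__all__ = [
    "ScanEvaluation",
    "FROCResult",
    "voxel_iou",
    "gt_components",
    "match_scan",
    "froc",
    "average_sensitivity",
    "DEFAULT_RATES",
]

DEFAULT_RATES = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclasses.dataclass
class ProposalRecord:
    confidence: float
    is_tp: bool
    matched_gt: int | None


@dataclasses.dataclass
class ScanEvaluation:
    scan_id: str
    n_gt: int
    records: list[ProposalRecord]


@dataclasses.dataclass
class FROCResult:
    rates: tuple[float, ...]
    sensitivities_pct: tuple[float, ...]
    average_pct: float
    curve: pd.DataFrame  # threshold, fps_per_scan, sensitivity


def _as_index_set(voxels: np.ndarray, shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Coerce a boolean mask or an (n, 3) coordinate array to flat indices."""
    voxels = np.asarray(voxels)
    if voxels.dtype == bool or (voxels.ndim == 3):
        return np.flatnonzero(voxels)
    if voxels.ndim == 2 and voxels.shape[1] == 3:
        if shape is None:
            raise ValueError("shape required to flatten coordinate arrays")
        return np.ravel_multi_index(voxels.T, shape)
    raise ValueError("voxel set must be a 3D boolean mask or an (n, 3) coordinate array")


def voxel_iou(a: np.ndarray, b: np.ndarray, shape: tuple[int, ...] | None = None) -> float:
    """|A∩B| / |A∪B| of two voxel sets on the same grid (not both empty)."""
    ia = _as_index_set(a, shape)
    ib = _as_index_set(b, shape)
    if ia.size == 0 and ib.size == 0:
        raise ValueError("IoU of two empty voxel sets is undefined")
    inter = np.intersect1d(ia, ib, assume_unique=False).size
    union = np.union1d(ia, ib).size
    return inter / union


def gt_components(mask: BinaryMask3D, connectivity: int = 26) -> list[np.ndarray]:
    """Connected components of an annotation mask as (n, 3) coordinate arrays."""
    from .preprocess import connectivity_structure

    labels, n = ndimage.label(mask.voxels, structure=connectivity_structure(connectivity))
    return [np.argwhere(labels == i).astype(np.int32) for i in range(1, n + 1)]


def match_scan(
    proposals: list[DetectionProposal],
    gt: list[np.ndarray],
    shape: tuple[int, int, int],
    iou_thresh: float = 0.2,
    scan_id: str = "",
) -> ScanEvaluation:
    """Greedy one-to-one proposal/lesion matching in confidence order."""
    order = sorted(proposals, key=lambda p: (-p.confidence, -p.volume, p.component_id))
    gt_idx = [np.ravel_multi_index(np.asarray(g).T, shape) for g in gt]
    unmatched = set(range(len(gt)))
    records = []
    for p in order:
        p_idx = np.ravel_multi_index(p.voxels.T, shape)
        best_iou, best_gt = 0.0, None
        for gi in unmatched:
            inter = np.intersect1d(p_idx, gt_idx[gi]).size
            if inter == 0:
                continue
            iou = inter / (p_idx.size + gt_idx[gi].size - inter)
            if iou > best_iou:
                best_iou, best_gt = iou, gi
        if best_gt is not None and best_iou > iou_thresh:
            unmatched.discard(best_gt)
            records.append(ProposalRecord(p.confidence, True, best_gt))
        else:
            records.append(ProposalRecord(p.confidence, False, None))
    return ScanEvaluation(scan_id=scan_id, n_gt=len(gt), records=records)


def froc(
    evaluations: list[ScanEvaluation], rates: tuple[float, ...] = DEFAULT_RATES
) -> FROCResult:
    """FROC curve and sensitivities at the requested FPs/scan rates."""
    if not evaluations:
        raise ValueError("no scans to evaluate")
    total_gt = sum(e.n_gt for e in evaluations)
    if total_gt < 1:
        raise ValueError("zero ground-truth lesions across all scans")
    n_scans = len(evaluations)
    records = [(r.confidence, r.is_tp) for e in evaluations for r in e.records]
    thresholds = sorted({c for c, _ in records}, reverse=True)
    rows = []
    for t in thresholds:
        tp = sum(1 for c, is_tp in records if c >= t and is_tp)
        fp = sum(1 for c, is_tp in records if c >= t and not is_tp)
        rows.append({"threshold": t, "fps_per_scan": fp / n_scans, "sensitivity": tp / total_gt})
    curve = pd.DataFrame(rows, columns=["threshold", "fps_per_scan", "sensitivity"])
    sens = []
    for r in rates:
        ok = curve[curve.fps_per_scan <= r] if len(curve) else curve
        sens.append(100.0 * float(ok.sensitivity.max()) if len(ok) else 0.0)
    return FROCResult(
        rates=tuple(rates),
        sensitivities_pct=tuple(sens),
        average_pct=float(np.mean(sens)),
        curve=curve,
    )


def average_sensitivity(sens_pct) -> float:
    """Mean of the five operating-point sensitivities, to 2 decimals."""
    sens_pct = list(sens_pct)
    if len(sens_pct) != len(DEFAULT_RATES):
        raise ValueError(f"expected {len(DEFAULT_RATES)} sensitivities, got {len(sens_pct)}")
    return round(float(np.mean(sens_pct)), 2)
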