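"""Whole-scan prediction and detection-proposal extraction.

A scan is covered by a sliding window of 96^3 voxels advancing 48 voxels per
axis; the final window on each axis is end-aligned so no voxel is missed, and
scans smaller than the window are zero-padded then cropped back. Windows that
contain no tissue (all normalized intensities ~0 — the background fill maps to
exactly 0 under the fixed bone window) are skipped. Overlapping window
predictions are fused by voxelwise averaging (max fusion available).

The fused probability map becomes detections by thresholding at 0.4,
26-connected component labeling, removal of components below 300 voxels, and
scoring each surviving component with its mean fused probability.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import connectivity_structure
from .volume import NormalizedVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SlidingWindowPlan",
    "DetectionProposal",
    "plan_windows",
    "predict_volume",
    "extract_proposals",
    "proposals_to_json",
    "proposals_from_json",
]


@dataclasses.dataclass
class SlidingWindowPlan:
    size: int
    step: int
    origins: list[tuple[int, int, int]]
    shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]


@dataclasses.dataclass
class DetectionProposal:
    """One candidate lesion: a connected super-threshold component."""

    scan_id: str
    confidence: float  # mean fused probability over the component
    volume: int  # voxel count
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # per-axis [lo, hi)
    voxels: np.ndarray  # (volume, 3) int voxel coordinates
    component_id: int = 0


def _axis_origins(dim: int, size: int, step: int) -> list[int]:
    if dim <= size:
        return [0]
    origins = list(range(0, dim - size + 1, step))
    if origins[-1] != dim - size:
        origins.append(dim - size)
    return origins


def plan_windows(shape: tuple[int, int, int], size: int = 96, step: int = 48) -> SlidingWindowPlan:
    """Enumerate window origins covering every voxel of the scan."""
    if any(s < 1 for s in shape):
        raise ValueError(f"invalid scan shape {shape}")
    padded = tuple(max(s, size) for s in shape)
    per_axis = [_axis_origins(d, size, step) for d in padded]
    origins = [tuple(o) for o in itertools.product(*per_axis)]
    return SlidingWindowPlan(size=size, step=step, origins=origins, shape=tuple(shape), padded_shape=padded)


def predict_volume(
    model,
    vol: NormalizedVolume,
    plan: SlidingWindowPlan | None = None,
    fusion: str = "mean",
    background_tol: float = 1e-6,
) -> np.ndarray:
    """Fused voxel-probability map for a whole preprocessed scan."""
    if fusion not in ("mean", "max"):
        raise ValueError("fusion must be 'mean' or 'max'")
    plan = plan or plan_windows(vol.shape)
    s = plan.size
    padded = np.zeros(plan.padded_shape, dtype=np.float32)
    padded[: vol.shape[0], : vol.shape[1], : vol.shape[2]] = vol.voxels
    acc = np.zeros(plan.padded_shape, dtype=np.float32)
    count = np.zeros(plan.padded_shape, dtype=np.int32)
    n_skipped = 0
    for origin in plan.origins:
        sl = tuple(slice(o, o + s) for o in origin)
        window = padded[sl]
        if not (window > background_tol).any():
            n_skipped += 1
            continue
        prob = model.forward(window[None, None], training=False)[0, 0]
        if fusion == "mean":
            acc[sl] += prob
            count[sl] += 1
        else:
            acc[sl] = np.maximum(acc[sl], prob)
            count[sl] += 1
    logger.info(
        "predict[%s]: %d windows forwarded, %d background windows skipped",
        vol.id, len(plan.origins) - n_skipped, n_skipped,
    )
    if fusion == "mean":
        fused = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    else:
        fused = acc
    return fused[: vol.shape[0], : vol.shape[1], : vol.shape[2]]


def extract_proposals(
    prob_map: np.ndarray,
    threshold: float = 0.4,
    min_voxels: int = 300,
    connectivity: int = 26,
    scan_id: str = "",
) -> list[DetectionProposal]:
    """Connected components of the thresholded map, small ones removed.

    Binarization is inclusive (probability >= threshold); components with
    strictly fewer than ``min_voxels`` voxels are dropped. Proposals are
    sorted by descending confidence with deterministic tie-breaks (larger
    volume first, then lower component id).
    """
    binary = prob_map >= threshold
    labels, n = ndimage.label(binary, structure=connectivity_structure(connectivity))
    proposals: list[DetectionProposal] = []
    if n == 0:
        return proposals
    sizes = np.bincount(labels.ravel())
    means = ndimage.mean(prob_map, labels=labels, index=np.arange(1, n + 1)) if n else []
    for comp_id in range(1, n + 1):
        vol = int(sizes[comp_id])
        if vol < min_voxels:
            continue
        coords = np.argwhere(labels == comp_id)
        bbox = tuple((int(coords[:, a].min()), int(coords[:, a].max()) + 1) for a in range(3))
        proposals.append(
            DetectionProposal(
                scan_id=scan_id,
                confidence=float(means[comp_id - 1]),
                volume=vol,
                bbox=bbox,
                voxels=coords.astype(np.int32),
                component_id=comp_id,
            )
        )
    proposals.sort(key=lambda p: (-p.confidence, -p.volume, p.component_id))
    return proposals


def proposals_to_json(proposals: list[DetectionProposal], path: str | Path) -> None:
    """Serialize proposals (with voxel coordinates) as JSON records."""
    records = [
        {
            "scan_id": p.scan_id,
            "confidence": p.confidence,
            "volume": p.volume,
            "bbox": [list(b) for b in p.bbox],
            "component_id": p.component_id,
            "voxels": p.voxels.tolist(),
        }
        for p in proposals
    ]
    Path(path).write_text(json.dumps(records))


def proposals_from_json(path: str | Path) -> list[DetectionProposal]:
    records = json.loads(Path(path).read_text())
    return [
        DetectionProposal(
            scan_id=r["scan_id"],
            confidence=float(r["confidence"]),
            volume=int(r["volume"]),
            bbox=tuple(tuple(b) for b in r["bbox"]),
            voxels=np.asarray(r["voxels"], dtype=np.int32).reshape(-1, 3),
            component_id=int(r.get("component_id", 0)),
        )
        for r in records
    ]
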