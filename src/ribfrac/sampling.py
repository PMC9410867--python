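"""Balanced patch sampling and spatial augmentation for training.

Fracture voxels are rare, so patches are drawn with a fixed positive
fraction (default 60%): a positive patch is centred on a uniformly chosen
voxel of a uniformly chosen ground-truth fracture component, jittered
uniformly per axis, and clipped to the scan bounds; a negative patch is
drawn uniformly over origins whose window contains some tissue and zero
fracture voxels. Whether a given draw is positive is an independent
Bernoulli(pos_fraction) event, so the positive share holds in expectation.

Augmentation applies, with one shared random state per sample, random axis
flips (p=1/2 each), a rotation of up to ±15° about one random axis, and an
isotropic affine scaling in [0.9, 1.1]. The identical transform is applied
to image and label; the image is interpolated linearly and the label with
nearest neighbour, then re-binarized.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage

from .volume import BinaryMask3D, NormalizedVolume

logger = logging.getLogger(__name__)

__all__ = ["PatchSample", "sample_patches", "augment"]


@dataclasses.dataclass
class PatchSample:
    """A cubic training patch cut from one scan."""

    image: np.ndarray  # (s, s, s) float32 in [0, 1]
    label: np.ndarray  # (s, s, s) uint8
    is_positive: bool
    origin: tuple[int, int, int]
    scan_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image/label shape mismatch")
        if bool(self.label.any()) != self.is_positive:
            raise ValueError("is_positive inconsistent with label content")


def _component_voxels(gt: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(gt, structure=np.ones((3, 3, 3), dtype=bool))
    out = []
    for i in range(1, n + 1):
        out.append(np.argwhere(labels == i))
    return out


def sample_patches(
    vol: NormalizedVolume,
    gt: BinaryMask3D,
    n_patches: int,
    patch_size: int = 96,
    pos_fraction: float = 0.6,
    jitter: int | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Yield ``n_patches`` seeded, reproducible patches from one scan."""
    if vol.shape != gt.shape:
        raise ValueError("volume and ground truth must be aligned")
    if not 0 <= pos_fraction <= 1:
        raise ValueError("pos_fraction must be in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    s = patch_size
    shape = np.array(vol.shape)
    if (shape < s).any():
        raise ValueError(f"scan {vol.shape} smaller than patch size {s}")
    jitter = s // 4 if jitter is None else jitter
    components = _component_voxels(gt.voxels)
    if not components and pos_fraction > 0:
        warnings.warn(f"scan {vol.id} has no fracture: emitting negatives only")
    img, lab = vol.voxels, gt.voxels
    max_origin = shape - s
    for _ in range(n_patches):
        want_pos = bool(components) and rng.random() < pos_fraction
        if want_pos:
            comp = components[rng.integers(len(components))]
            centre = comp[rng.integers(len(comp))]
            origin = centre - s // 2 + rng.integers(-jitter, jitter + 1, size=3)
            origin = np.clip(origin, 0, max_origin)
            # jitter can in principle push the lesion out; nudge back if so
            for _retry in range(20):
                sl = tuple(slice(o, o + s) for o in origin)
                if lab[sl].any():
                    break
                origin = np.clip(centre - s // 2, 0, max_origin)
        else:
            for _retry in range(200):
                origin = rng.integers(0, max_origin + 1, size=3)
                sl = tuple(slice(o, o + s) for o in origin)
                if not lab[sl].any() and (img[sl] > 1e-6).any():
                    break
            else:
                raise RuntimeError(f"could not draw a negative tissue patch from scan {vol.id}")
        sl = tuple(slice(o, o + s) for o in origin)
        patch_lab = lab[sl].copy()
        yield PatchSample(
            image=img[sl].copy(),
            label=patch_lab,
            is_positive=bool(patch_lab.any()),
            origin=tuple(int(o) for o in origin),
            scan_id=vol.id,
        )


def augment(
    sample: PatchSample,
    rng: np.random.Generator | int | None = None,
    rotate_deg: float = 15.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    flip: bool = True,
) -> PatchSample:
    """Random flip + rotation + isotropic scaling of a patch and its label."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    img = sample.image.astype(np.float32)
    lab = sample.label

    angle = rng.uniform(-rotate_deg, rotate_deg)
    axis = int(rng.integers(3))
    scale = rng.uniform(*scale_range)
    flips = rng.random(3) < 0.5 if flip else np.zeros(3, dtype=bool)

    if rotate_deg > 0 or scale != 1.0:
        theta = np.deg2rad(angle)
        c, s_ = np.cos(theta), np.sin(theta)
        rot = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        rot[i, i], rot[i, j], rot[j, i], rot[j, j] = c, -s_, s_, c
        # affine_transform maps output coords through the matrix: use the
        # inverse of (rot * scale) about the patch centre
        matrix = rot.T / scale
        centre = (np.array(img.shape) - 1) / 2.0
        offset = centre - matrix @ centre
        img = ndimage.affine_transform(img, matrix, offset=offset, order=1, mode="constant", cval=0.0)
        lab = ndimage.affine_transform(lab, matrix, offset=offset, order=0, mode="constant", cval=0)
        img = np.clip(img, 0.0, 1.0)
        lab = (lab > 0).astype(np.uint8)

    for ax in range(3):
        if flips[ax]:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)

    return PatchSample(
        image=np.ascontiguousarray(img),
        label=np.ascontiguousarray(lab),
        is_positive=bool(lab.any()),
        origin=sample.origin,
        scan_id=sample.scan_id,
    )
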