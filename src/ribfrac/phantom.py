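"""Synthetic chest-CT phantoms with ground-truth rib-fracture masks.

The phantom reproduces, in simplified geometry, exactly the structure the
detection pipeline relies on: a soft-tissue thorax in air; a posterior
spine column and a cage of curved rib tubes whose HU exceeds the 180 HU
bone threshold, with every rib attached to the spine so that the cage
survives largest-component extraction; a handful of small bright debris
components individually below the 4000 mm^3 size filter; and per scan a
few "fracture" lesions — short transverse bands on a rib where the bone
intensity drops to a configurable dip value — recorded in a voxel-accurate
ground-truth mask.

The fracture dip defaults to 200 HU: visibly disrupted against the ~700 HU
cortex and ~250 HU marrow, yet still above the 180 HU extraction threshold
so a lesion can never fall out of the bone mask. Gaussian noise (sd 15 HU)
is added everywhere. What the phantom deliberately does *not* model: lungs,
heart, vessels, partial-volume blur, reconstruction-kernel texture, or
anatomically scaled rib counts; see the methods note for what that implies
for conclusions drawn from phantom experiments.

All geometry is rasterised deterministically from a single seed; dataset
generation derives one child seed per scan and writes a manifest so any
scan can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import BinaryMask3D, CTVolume, write_nifti

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclasses.dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the synthetic thorax (HU, voxels).

    ``n_fractures`` and ``fracture_extent`` are inclusive (lo, hi) ranges
    sampled per scan / per lesion. The fracture extent is capped by
    ``__post_init__`` only through validation of user values, not silently.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_rib_pairs: int = 6
    rib_radius: float = 5.0
    rib_cortical_hu: float = 700.0
    rib_marrow_hu: float = 250.0
    cortex_thickness: float = 2.0
    spine_hu: float = 600.0
    spine_radius: float = 6.0
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    n_fractures: tuple[int, int] = (2, 5)
    fracture_extent: tuple[int, int] = (4, 6)
    fracture_hu: float = 200.0
    n_debris: int = 5
    debris_hu: float = 500.0
    debris_radius: tuple[float, float] = (2.0, 4.0)
    noise_sd_hu: float = 15.0

    def __post_init__(self) -> None:
        if min(self.shape) < 48:
            raise ValueError(f"phantom shape {self.shape} too small (minimum 48 per axis)")
        if self.shape[0] < (self.n_rib_pairs + 1) * 2 * (self.rib_radius + 2):
            raise ValueError(
                f"shape {self.shape} too small along axis 0 for {self.n_rib_pairs} rib pairs"
            )
        if self.fracture_extent[0] < 1 or self.fracture_extent[1] < self.fracture_extent[0]:
            raise ValueError("fracture_extent must be an increasing positive range")
        if self.n_fractures[0] < 0 or self.n_fractures[1] < self.n_fractures[0]:
            raise ValueError("n_fractures must be a nonnegative increasing range")

    @classmethod
    def easy(cls, shape: tuple[int, int, int] = (96, 96, 96)) -> "PhantomConfig":
        """Few, large, well-separated lesions on thick ribs; lower noise.

        The setting used for scaled-down end-to-end exercises: fracture
        bands span the full 5-voxel-radius rib over 5-6 voxels of extent
        (~400+ voxel lesions, comfortably above the 300-voxel proposal
        filter) and the dip is deeper relative to the noise floor.
        """
        return cls(
            shape=shape,
            n_rib_pairs=4,
            n_fractures=(2, 3),
            fracture_extent=(5, 6),
            noise_sd_hu=10.0,
            n_debris=3,
        )


def _rib_centerline(
    centre: np.ndarray,
    radii: np.ndarray,
    z0: float,
    spine_xy: np.ndarray,
    side: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one rib: an elliptical arc plus a straight connector to the spine.

    Returns an (n, 3) float array of finely spaced points in voxel space.
    ``side`` is +1 (left) or -1 (right); the arc starts just lateral of the
    spine and sweeps around the thorax toward the anterior.
    """
    # angles measured from +x axis in the (x=axis1, y=axis2) plane; the spine
    # sits posterior at angle ~90 deg
    start = np.deg2rad(90 - side * rng.uniform(18, 25))
    stop = np.deg2rad(90 - side * rng.uniform(175, 200))
    thetas = np.linspace(start, stop, 300)
    slope = rng.uniform(0.0, 4.0)  # ribs droop a few voxels toward anterior
    frac = np.linspace(0, 1, thetas.size)
    pts = np.stack(
        [
            z0 + slope * frac,
            centre[0] + radii[0] * np.cos(thetas),
            centre[1] + radii[1] * np.sin(thetas),
        ],
        axis=1,
    )
    # connector: straight segment from the arc's posterior end to the spine axis
    head = pts[0, 1:]
    seg = np.linspace(0, 1, 40)[:, None]
    connector = np.concatenate(
        [np.full((40, 1), z0), head[None, :] * (1 - seg) + spine_xy[None, :] * seg], axis=1
    )
    return np.concatenate([connector, pts], axis=0)


def _paint_tube(
    shape: tuple[int, int, int], centerline: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Voxels within ``radius`` of the centerline; returns (coords, distances)."""
    lo = np.maximum(np.floor(centerline.min(axis=0) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(centerline.max(axis=0) + radius).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1)
    dist, _ = cKDTree(centerline).query(coords, k=1)
    keep = dist <= radius
    return coords[keep], dist[keep]


def generate_phantom(
    cfg: PhantomConfig | None = None, seed: int = 0, scan_id: str = "phantom"
) -> tuple[CTVolume, BinaryMask3D]:
    """Build one phantom scan and its fracture ground-truth mask."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    Z, X, Y = cfg.shape
    vol = np.full(cfg.shape, cfg.air_hu, dtype=np.float32)

    # soft-tissue body: elliptical cylinder along axis 0
    cx, cy = (X - 1) / 2.0, (Y - 1) / 2.0
    rx, ry = 0.44 * X, 0.40 * Y
    xs, ys = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    body2d = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
    vol[:, body2d] = cfg.soft_tissue_hu

    # spine: posterior circular column along axis 0
    spine_xy = np.array([cx, cy + 0.62 * ry])
    spine2d = (xs - spine_xy[0]) ** 2 + (ys - spine_xy[1]) ** 2 <= cfg.spine_radius**2
    vol[:, spine2d] = cfg.spine_hu
    bone = np.zeros(cfg.shape, dtype=bool)
    bone[:, spine2d] = True

    # ribs: per pair, one left + one right tube with cortical shell and marrow
    z_levels = np.linspace(0.15 * Z, 0.85 * Z, cfg.n_rib_pairs)
    rib_tubes: list[tuple[np.ndarray, np.ndarray]] = []  # (coords, centerline)
    arc_radii = np.array([0.80 * rx, 0.74 * ry])
    for z0 in z_levels:
        for side in (+1, -1):
            line = _rib_centerline(np.array([cx, cy]), arc_radii, z0, spine_xy, side, rng)
            coords, dist = _paint_tube(cfg.shape, line, cfg.rib_radius)
            idx = tuple(coords.T)
            hu = np.where(
                dist >= cfg.rib_radius - cfg.cortex_thickness,
                cfg.rib_cortical_hu,
                cfg.rib_marrow_hu,
            ).astype(np.float32)
            vol[idx] = hu
            bone[idx] = True
            rib_tubes.append((coords, line))

    # fractures: transverse dip bands on distinct ribs, away from both rib ends
    n_frac = int(rng.integers(cfg.n_fractures[0], cfg.n_fractures[1] + 1))
    if n_frac > len(rib_tubes):
        raise ValueError(f"cannot place {n_frac} fractures on {len(rib_tubes)} ribs")
    gt = np.zeros(cfg.shape, dtype=np.uint8)
    rib_choice = rng.choice(len(rib_tubes), size=n_frac, replace=False)
    for ri in rib_choice:
        coords, line = rib_tubes[ri]
        # pick a centerline point in the middle 50% of the arc (skip connector)
        n_line = len(line)
        j = int(rng.integers(int(0.4 * n_line), int(0.85 * n_line)))
        p_star = line[j]
        tangent = line[min(j + 1, n_line - 1)] - line[max(j - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        extent = int(rng.integers(cfg.fracture_extent[0], cfg.fracture_extent[1] + 1))
        along = (coords - p_star) @ tangent
        near = np.linalg.norm(coords - p_star, axis=1) <= (extent / 2 + cfg.rib_radius + 1)
        band = (np.abs(along) <= extent / 2) & near
        idx = tuple(coords[band].T)
        vol[idx] = cfg.fracture_hu
        gt[idx] = 1

    # debris: small bright blobs not touching the cage
    placed = 0
    attempts = 0
    debris_voxels = 0
    while placed < cfg.n_debris and attempts < 200:
        attempts += 1
        r = rng.uniform(*cfg.debris_radius)
        margin = int(np.ceil(r)) + 2
        c = np.array(
            [
                rng.integers(margin, Z - margin),
                rng.integers(margin, X - margin),
                rng.integers(margin, Y - margin),
            ]
        )
        if not body2d[c[1], c[2]]:
            continue
        lo = (c - margin).astype(int)
        hi = (c + margin + 1).astype(int)
        zz, xx, yy = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        ball = (zz - c[0]) ** 2 + (xx - c[1]) ** 2 + (yy - c[2]) ** 2 <= r**2
        region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        # keep a 2-voxel clearance so debris never merges with the cage
        near_bone = bone[
            max(lo[0] - 2, 0) : hi[0] + 2, max(lo[1] - 2, 0) : hi[1] + 2, max(lo[2] - 2, 0) : hi[2] + 2
        ].any()
        if near_bone:
            continue
        ball_mm3 = ball.sum() * float(np.prod(cfg.spacing))
        if ball_mm3 >= 4000.0:
            continue
        vol[region][ball] = cfg.debris_hu
        debris_voxels += int(ball.sum())
        placed += 1
    if placed < cfg.n_debris:
        logger.warning("placed only %d/%d debris components", placed, cfg.n_debris)

    if cfg.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd_hu, size=cfg.shape).astype(np.float32)

    ct = CTVolume(vol.astype(np.float32), cfg.spacing, id=scan_id)
    mask = BinaryMask3D(gt, cfg.spacing, id=scan_id)
    return ct, mask


def generate_dataset(
    n_scans: int,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate ``n_scans`` phantoms; optionally write NIfTI pairs + manifest.

    Per-scan seeds are ``seed + 1000 * i`` so each scan regenerates
    independently of the others. Returns the manifest; when ``out_dir`` is
    given, ``<id>.nii.gz``/``<id>_label.nii.gz`` pairs and ``manifest.csv``
    are written there.
    """
    from scipy import ndimage

    cfg = cfg or PhantomConfig()
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_scans):
        scan_seed = seed + 1000 * i
        scan_id = f"scan{i:03d}"
        ct, gt = generate_phantom(cfg, seed=scan_seed, scan_id=scan_id)
        _, n_comp = ndimage.label(gt.voxels, structure=np.ones((3, 3, 3), dtype=bool))
        rows.append({"id": scan_id, "seed": scan_seed, "n_gt_components": int(n_comp)})
        if out_dir is not None:
            write_nifti(ct, out_dir / f"{scan_id}.nii.gz")
            write_nifti(gt, out_dir / f"{scan_id}_label.nii.gz")
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
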