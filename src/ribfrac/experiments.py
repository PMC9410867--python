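"""Scaled-down end-to-end detection experiment on synthetic phantoms.

A single-CPU smoke version of the full recipe: simulate easy-setting
phantoms, preprocess them, train a narrow model on 48^3 patches, run
sliding-window inference on held-out scans and score the detections with
FROC. Everything is driven by one seed; see docs/methods.md for why these
problem sizes and why the expectations on the outcome are loose.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .froc import FROCResult, froc, gt_components, match_scan
from .inference import extract_proposals, predict_volume
from .nn import ModelConfig
from .phantom import PhantomConfig, generate_phantom
from .preprocess import preprocess_pipeline
from .train import TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = ["SmokeResult", "run_smoke_detection_experiment"]


@dataclasses.dataclass
class SmokeResult:
    history: pd.DataFrame
    froc_result: FROCResult
    n_test_scans: int
    n_gt_lesions: int
    n_proposals: int

    @property
    def initial_train_loss(self) -> float:
        return float(self.history.train_loss.iloc[0])

    @property
    def final_train_loss(self) -> float:
        return float(self.history.train_loss.iloc[-1])

    @property
    def sensitivity_at_8fps_pct(self) -> float:
        return float(self.froc_result.sensitivities_pct[-1])


def run_smoke_detection_experiment(
    seed: int = 1,
    n_scans: int = 10,
    n_test: int = 2,
    epochs: int = 5,
    steps_per_epoch: int = 40,
    batch_size: int = 4,
    base_channels: int = 4,
    patch_size: int = 48,
) -> SmokeResult:
    """Simulate, preprocess, train, predict and score; seeded throughout.

    The last ``n_test`` scans are held out for FROC scoring, the scan before
    them is the validation scan, the rest train (a 7:1:2 split at the default
    ``n_scans=10``).
    """
    phantom_cfg = PhantomConfig.easy()
    scans = []
    for i in range(n_scans):
        ct, gt = generate_phantom(phantom_cfg, seed=seed + 1000 * i, scan_id=f"scan{i:03d}")
        normalized, _ = preprocess_pipeline(ct)
        scans.append((normalized, gt))
    n_val = 1
    train_scans = scans[: n_scans - n_test - n_val]
    val_scans = scans[n_scans - n_test - n_val : n_scans - n_test]
    test_scans = scans[n_scans - n_test :]
    logger.info(
        "smoke experiment: %d train / %d val / %d test scans",
        len(train_scans), len(val_scans), len(test_scans),
    )

    model_cfg = ModelConfig(base_channels=base_channels, seed=seed)
    # augmentation is off at this scale: with a few hundred steps on the easy
    # phantom its regularisation only delays the fit, and the smoke run checks
    # pipeline composition and learnability, not generalisation
    train_cfg = TrainConfig(
        batch_size=batch_size,
        epochs=epochs,
        steps_per_epoch=steps_per_epoch,
        patch_size=patch_size,
        val_batches=1,
        augment=False,
        seed=seed,
    )
    result = train(train_scans, model_cfg, train_cfg, val_dataset=val_scans)

    evaluations = []
    n_proposals = 0
    for normalized, gt in test_scans:
        prob = predict_volume(result.model, normalized)
        proposals = extract_proposals(prob, threshold=0.4, min_voxels=300, scan_id=normalized.id)
        n_proposals += len(proposals)
        comps = gt_components(gt)
        evaluations.append(match_scan(proposals, comps, gt.shape, scan_id=normalized.id))
    froc_result = froc(evaluations)
    return SmokeResult(
        history=result.history,
        froc_result=froc_result,
        n_test_scans=len(test_scans),
        n_gt_lesions=sum(e.n_gt for e in evaluations),
        n_proposals=n_proposals,
    )
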