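"""Training loop: balanced sampling, augmentation, Adam, best-checkpoint keep.

Scans are split 7:1:2 into train/validation/test by scan id (never by patch,
so no scan leaks across splits). Each optimisation step draws a batch of
patches from randomly chosen training scans at the configured positive
fraction, augments them, and takes one Adam step on the Dice + weighted-BCE
objective. A fixed, seeded set of validation patches is scored after every
epoch; the checkpoint with the lowest validation total loss is kept.
Everything downstream of the single seed is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import total_loss, total_loss_grad
from .nn import Adam, AttentionResUNet3D, ModelConfig, save_checkpoint
from .sampling import augment, sample_patches
from .volume import BinaryMask3D, NormalizedVolume

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainResult", "split_scans", "train"]


@dataclasses.dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    The optimizer is Adam with beta1=0.9, beta2=0.999, eps=1e-8, initial
    learning rate 1e-3 and weight decay 1e-4. ``pos_fraction`` is the
    expected share of fracture-containing patches per draw. ``epochs`` and
    ``steps_per_epoch`` control the schedule; an epoch here is a fixed number
    of sampled-batch steps, not a sweep of a finite patch list.
    """

    batch_size: int = 16
    epochs: int = 100
    steps_per_epoch: int = 25
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 1e-4
    pos_fraction: float = 0.6
    patch_size: int = 96
    augment: bool = True
    rotate_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    val_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pos_fraction <= 1:
            raise ValueError("pos_fraction must be in [0, 1]")
        for name in ("batch_size", "epochs", "steps_per_epoch", "patch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("learning_rate", "adam_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class TrainResult:
    model: AttentionResUNet3D
    history: pd.DataFrame  # epoch, train_loss, train_dice, train_wbce, val_loss
    best_epoch: int
    best_val_loss: float
    checkpoint_path: Path | None


def split_scans(
    scan_ids: list[str], ratios: tuple[float, float, float] = (0.7, 0.1, 0.2), seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Shuffle scan ids and split by the given train/val/test ratios.

    Each nonempty-ratio split receives at least one scan when possible.
    """
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError("ratios must sum to 1")
    ids = list(scan_ids)
    np.random.default_rng(seed).shuffle(ids)
    n = len(ids)
    n_val = max(1, round(ratios[1] * n)) if ratios[1] > 0 and n > 1 else 0
    n_test = max(1, round(ratios[2] * n)) if ratios[2] > 0 and n > 2 else 0
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError(f"too few scans ({n}) for a {ratios} split")
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


def _draw_batch(scans, cfg: TrainConfig, rng: np.random.Generator, do_augment: bool):
    images, labels = [], []
    for _ in range(cfg.batch_size):
        vol, gt = scans[rng.integers(len(scans))]
        (patch,) = sample_patches(
            vol, gt, 1, cfg.patch_size, cfg.pos_fraction, rng=rng
        )
        if do_augment:
            patch = augment(patch, rng, cfg.rotate_deg, cfg.scale_range)
        images.append(patch.image)
        labels.append(patch.label)
    x = np.stack(images)[:, None].astype(np.float32)
    y = np.stack(labels)[:, None].astype(np.float32)
    return x, y


def train(
    dataset: list[tuple[NormalizedVolume, BinaryMask3D]],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_dataset: list[tuple[NormalizedVolume, BinaryMask3D]] | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainResult:
    """Train a segmentation model on preprocessed scans.

    ``dataset`` holds the training scans. If ``val_dataset`` is None the
    dataset is split 7:1:2 by scan and the test share is simply held out
    (returned splits are logged); otherwise the provided scans are used for
    validation as-is.
    """
    if not dataset:
        raise ValueError("empty dataset")
    model_cfg = model_cfg or ModelConfig()
    cfg = train_cfg or TrainConfig()

    if val_dataset is None:
        by_id = {vol.id: (vol, gt) for vol, gt in dataset}
        train_ids, val_ids, test_ids = split_scans(list(by_id), seed=cfg.seed)
        logger.info("scan split: train=%s val=%s test(held out)=%s", train_ids, val_ids, test_ids)
        train_scans = [by_id[i] for i in train_ids]
        val_scans = [by_id[i] for i in val_ids] or train_scans
    else:
        train_scans = list(dataset)
        val_scans = list(val_dataset)

    model = AttentionResUNet3D(model_cfg)
    optim = Adam(
        model.params(),
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        eps=cfg.adam_eps,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    # fixed validation batches, same patches every epoch
    val_rng = np.random.default_rng(cfg.seed + 1)
    val_batches = [
        _draw_batch(val_scans, cfg, val_rng, do_augment=False) for _ in range(cfg.val_batches)
    ]

    rows = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    for epoch in range(cfg.epochs):
        tr_tot, tr_dice, tr_wbce = 0.0, 0.0, 0.0
        for _ in range(cfg.steps_per_epoch):
            x, y = _draw_batch(train_scans, cfg, rng, do_augment=cfg.augment)
            prob = model.forward(x, training=True)
            lv = total_loss(prob, y)
            model.zero_grad()
            model.backward(total_loss_grad(prob, y))
            optim.step()
            tr_tot += lv.total
            tr_dice += lv.dice
            tr_wbce += lv.wbce
        n = cfg.steps_per_epoch
        val = float(
            np.mean([total_loss(model.forward(x, training=False), y).total for x, y in val_batches])
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": tr_tot / n,
                "train_dice": tr_dice / n,
                "train_wbce": tr_wbce / n,
                "val_loss": val,
            }
        )
        logger.info("epoch %d: train %.4f val %.4f", epoch, tr_tot / n, val)
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if best_state is not None:
        model.load_state_dict(best_state)
    ckpt_path = None
    if checkpoint_dir is not None:
        ckpt_path = Path(checkpoint_dir) / "best.npz"
        save_checkpoint(model, ckpt_path)
        pd.DataFrame(rows).to_csv(Path(checkpoint_dir) / "history.csv", index=False)
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=best_val,
        checkpoint_path=ckpt_path,
    )
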