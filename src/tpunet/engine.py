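"""Training loop, checkpointing, learning-rate schedule, and prediction.

Training follows the published recipe: Adam starting at 0.003, the
validation mean IoU is monitored every epoch, parameters are saved
whenever it improves, and the learning rate is halved after a
configurable number of epochs (default 30) without improvement. The
boundary-loss weight follows the epoch schedule in
:mod:`tpunet.losses`. Everything (initialization, data order,
augmentation) is driven by the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import data as busi
from . import losses as L
from . import metrics
from .arch import ArchConfig, TPUNet
from .nn import Adam, Tensor
from .phantoms import PhantomParams, generate_phantom

try:  # pin BLAS to one thread during training: loss curves become
    # bit-reproducible regardless of the host's core count
    from threadpoolctl import threadpool_limits as _threadpool_limits
except ImportError:  # pragma: no cover
    from contextlib import nullcontext

    def _threadpool_limits(limits=None):
        return nullcontext()

__all__ = ["TrainConfig", "train", "predict", "save_checkpoint", "load_checkpoint", "build_pairs"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Everything a training run needs; see field comments for units."""

    arch: ArchConfig = field(default_factory=ArchConfig)
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    start_lr: float = 0.003
    lr_patience: int = 30  # epochs without val-mIoU improvement before halving
    max_epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    checkpoint_dir: str = "checkpoints"
    # data source: "phantom" generates in memory, "busi" reads a directory tree
    source: str = "phantom"
    data_root: str | None = None
    include_normal: bool = False  # tumor-free class excluded by default
    target_size: int = 224  # BUSI preprocessing size
    augment: bool = True  # random flip/rotation on training batches
    rotation_degrees: float = 15.0
    phantom: PhantomParams = field(default_factory=lambda: PhantomParams(image_size=64))
    n_train: int = 64
    n_val: int = 16
    n_test: int = 16
    postprocess: bool = True
    stop_miou: float | None = None  # stop once val mIoU reaches this value

    def __post_init__(self):
        if self.start_lr <= 0:
            raise ValueError("start_lr must be positive")
        if self.lr_patience < 1:
            raise ValueError("lr_patience must be >= 1")


def _normalize(image: np.ndarray) -> np.ndarray:
    return ((image - 0.5) / 0.5).astype(np.float32)


def build_pairs(config: TrainConfig):
    """Materialize (train, val, test) lists of normalized (image, mask) pairs."""
    if config.source == "phantom":
        n_total = config.n_train + config.n_val + config.n_test
        pairs = []
        for k in range(1, n_total + 1):
            img, mask = generate_phantom(config.phantom, k)
            pairs.append((_normalize(img), mask))
        tr = pairs[: config.n_train]
        va = pairs[config.n_train : config.n_train + config.n_val]
        te = pairs[config.n_train + config.n_val :]
        return tr, va, te
    if config.source != "busi":
        raise ValueError("source must be 'phantom' or 'busi'")
    if not config.data_root:
        raise ValueError("busi source needs data_root")
    records = busi.discover_cases(config.data_root)
    if not config.include_normal:
        records = [r for r in records if r.class_label != "normal"]
    kept, _ = busi.filter_single_mask(records)
    splits = busi.split_cases(kept, busi.SplitSpec(seed=config.seed))
    pre = busi.PreprocConfig(target_size=config.target_size)
    out = []
    for part in splits:
        out.append([busi.preprocess_case(r, pre) for r in part])
    return tuple(out)


def _batch(pairs, idx):
    images = np.stack([pairs[i][0] for i in idx])[:, None]
    masks = np.stack([pairs[i][1] for i in idx]).astype(np.float32)[:, None]
    return images, masks


def _augment_batch(images, masks, rng, max_degrees):
    """Random flip + rotation on normalized batches (published recipe).

    Images are zero-centered, so rotation fills with -1 (black); masks
    rotate nearest-neighbor and stay binary.
    """
    from scipy.ndimage import rotate as _rotate

    for i in range(images.shape[0]):
        if rng.uniform() < 0.5:
            images[i, 0] = images[i, 0, :, ::-1]
            masks[i, 0] = masks[i, 0, :, ::-1]
        angle = float(rng.uniform(-max_degrees, max_degrees))
        if angle != 0.0 and max_degrees > 0:
            images[i, 0] = _rotate(images[i, 0], angle, reshape=False, order=1, cval=-1.0, prefilter=False)
            rot = _rotate(masks[i, 0], angle, reshape=False, order=0, cval=0.0, prefilter=False)
            masks[i, 0] = (rot > 0.5).astype(np.float32)
    return images, masks


def save_checkpoint(model: TPUNet, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(model.state_dict())
    payload["__meta"] = np.frombuffer(
        json.dumps({"arch": model.config.to_dict(), **(meta or {})}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[TPUNet, dict]:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files if k != "__meta"}
        meta = json.loads(bytes(archive["__meta"]).decode())
    model = TPUNet(ArchConfig.from_dict(meta["arch"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta


def train(config: TrainConfig, pairs=None) -> tuple[pd.DataFrame, Path]:
    """Run the full loop; returns the per-epoch history and the best
    checkpoint path. ``pairs`` may inject pre-built (train, val, test)
    lists (the test list is unused here)."""
    train_pairs, val_pairs, _ = pairs if pairs is not None else build_pairs(config)
    if not train_pairs or not val_pairs:
        raise ValueError("empty train or validation split")

    rng = np.random.default_rng(config.seed)
    model = TPUNet(config.arch, seed=config.seed)
    optimizer = Adam(model.parameters(), lr=config.start_lr)
    ckpt_dir = Path(config.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    best_path = ckpt_dir / "best.npz"

    best_miou = -np.inf
    epochs_since_best = 0
    rows = []

    with _threadpool_limits(limits=1):
        for epoch in range(config.max_epochs):
            model.train()
            order = rng.permutation(len(train_pairs))
            sums = {"total": 0.0, "deepsup": 0.0, "focal": 0.0, "focal_tversky": 0.0, "hd": 0.0}
            n_batches = 0
            alpha = L.hd_alpha(epoch, config.loss)
            for start in range(0, len(order), config.batch_size):
                idx = order[start : start + config.batch_size]
                images, masks = _batch(train_pairs, idx)
                if config.augment:
                    images, masks = _augment_batch(images, masks, rng, config.rotation_degrees)
                out = model(Tensor(images))
                ds = L.deep_supervision_loss(out.deepsup, masks, config.loss)
                fl = L.focal_loss(out.prediction, masks, config.loss)
                ftv = L.focal_tversky_loss(out.prediction, masks, config.loss)
                parts = {"deepsup": ds, "focal": fl, "focal_tversky": ftv}
                seg = fl + ftv
                if alpha > 0:
                    hdl = L.hd_loss(out.prediction, masks)
                    parts["hd"] = hdl
                    seg = seg + alpha * hdl
                total = ds + config.loss.lambda_seg * seg
                for name, value in {**parts, "total": total}.items():
                    v = value.item()
                    if not np.isfinite(v):
                        raise RuntimeError(f"non-finite training loss in component '{name}' at epoch {epoch}")
                    sums[name] += v
                optimizer.zero_grad()
                total.backward()
                optimizer.step()
                n_batches += 1

            report = metrics.evaluate(model.predict_proba, val_pairs, postprocess=config.postprocess)
            improved = report.miou > best_miou
            if improved:
                best_miou = report.miou
                epochs_since_best = 0
                save_checkpoint(model, best_path, {"val_miou": report.miou, "epoch": epoch,
                                                   "target_size": config.target_size
                                                   if config.source == "busi" else config.phantom.image_size})
            else:
                epochs_since_best += 1
            halved = False
            if epochs_since_best >= config.lr_patience:
                optimizer.lr *= 0.5
                epochs_since_best = 0
                halved = True
                logger.info("epoch %d: halving learning rate to %g", epoch, optimizer.lr)

            rows.append(
                {
                    "epoch": epoch,
                    **{f"loss_{k}": v / n_batches for k, v in sums.items()},
                    "val_miou": report.miou,
                    "val_mhd95": report.mhd95,
                    "lr": optimizer.lr,
                    "checkpoint": improved,
                    "lr_halved": halved,
                }
            )
            logger.info(
                "epoch %d: loss %.4f, val mIoU %.4f, val mHD95 %.2f",
                epoch, rows[-1]["loss_total"], report.miou, report.mhd95,
            )
            if config.stop_miou is not None and best_miou >= config.stop_miou:
                break

    history = pd.DataFrame(rows)
    history.to_csv(ckpt_dir / "history.csv", index=False)
    return history, best_path


def predict(checkpoint, image_path, out_path, threshold: float = 0.5, postprocess: bool = True) -> np.ndarray:
    """Segment a single PNG with a trained checkpoint.

    Applies the training-time geometry (pad to square, resize to the
    checkpoint's input size), runs the network, thresholds, optionally
    keeps the largest component, maps the mask back to the original
    geometry, and writes an 8-bit PNG. Returns the mask array.
    """
    model, meta = load_checkpoint(checkpoint)
    size = int(meta.get("target_size", 224))
    image = np.asarray(Image.open(image_path).convert("L"), dtype=np.float32) / 255.0
    h, w = image.shape
    side = max(h, w)
    padded, _ = busi.pad_to_square(image, np.zeros_like(image, dtype=np.uint8))
    resized, _ = busi.resize_pair(padded, np.zeros_like(padded, dtype=np.uint8), size)
    prob = model.predict_proba(_normalize(resized)[None, None])[0, 0]
    mask = (prob > threshold).astype(np.uint8)
    if postprocess:
        mask = metrics.largest_component(mask)
    # undo resize and padding (nearest-neighbor keeps the mask binary)
    _, back = busi.resize_pair(mask.astype(np.float32), mask, side)
    full = back[:h, :w]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(full * 255, mode="L").save(out_path)
    return full
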