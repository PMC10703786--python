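"""BUSI-layout dataset handling: discovery, filtering, splits, preprocessing.

The public breast-ultrasound dataset ships PNGs as ``<class>/<class>
(k).png`` with masks ``<class> (k)_mask.png`` (and ``_mask_1.png`` etc.
when a scan has several annotated lesions). Cases with multiple masks
need multiple segmentation targets and are excluded from single-lesion
training rather than merged. The split rule is: ``round(f_train * n)``
training cases, the remainder divided evenly between validation and
test with an odd leftover going to validation — the rule that
reproduces the published count triples (421 -> 253/84/84 and
209 -> 125/42/42) exactly.

Images are loaded as single-channel luminance in [0, 1]; preprocessing
pads to a square with black (top-left anchored), resizes to the target
size (bilinear for images, nearest-neighbor for masks so they stay
binary), and augments with random horizontal flips and small rotations
before normalizing the image to zero-centered [-1, 1].
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "CaseRecord",
    "SplitSpec",
    "PreprocConfig",
    "discover_cases",
    "filter_single_mask",
    "split_sizes",
    "split_cases",
    "load_pair",
    "pad_to_square",
    "resize_pair",
    "normalize_image",
    "augment_pair",
    "preprocess_case",
    "save_split_manifests",
]

logger = logging.getLogger(__name__)

_CLASSES = ("benign", "malignant", "normal", "phantom")
_MASK_RE = re.compile(r"^(?P<stem>.+?)_mask(_\d+)?$")


@dataclass(frozen=True)
class CaseRecord:
    """One base image with its mask annotation files."""

    image_path: Path
    mask_paths: tuple[Path, ...]
    class_label: str
    case_id: str

    @property
    def n_masks(self) -> int:
        return len(self.mask_paths)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions (must sum to 1) and the shuffle seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if min(self.fractions) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(self.fractions)}")


@dataclass(frozen=True)
class PreprocConfig:
    """Target geometry, augmentation flags, and normalization constants."""

    target_size: int = 224
    hflip: bool = True
    rotation_degrees: float = 15.0
    normalize: bool = True
    norm_mean: float = 0.5
    norm_std: float = 0.5

    def __post_init__(self):
        if self.target_size % 8 != 0:
            raise ValueError("target_size must be divisible by 8 (three 2x downsamplings)")


# ---------------------------------------------------------------------------
# discovery / filtering / splitting
# ---------------------------------------------------------------------------

def discover_cases(root) -> list[CaseRecord]:
    """Walk class subdirectories and pair each base PNG with its masks.

    An image without any mask file is still returned (with no masks)
    but a warning is logged so the gap is visible.
    """
    root = Path(root)
    records: list[CaseRecord] = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        label = class_dir.name.lower()
        if label not in _CLASSES:
            continue
        masks_by_stem: dict[str, list[Path]] = {}
        images: list[Path] = []
        for png in sorted(class_dir.glob("*.png")):
            m = _MASK_RE.match(png.stem)
            if m:
                masks_by_stem.setdefault(m.group("stem"), []).append(png)
            else:
                images.append(png)
        for img in images:
            masks = tuple(sorted(masks_by_stem.get(img.stem, [])))
            if not masks:
                logger.warning("no mask found for %s", img)
            records.append(
                CaseRecord(image_path=img, mask_paths=masks, class_label=label, case_id=f"{label}/{img.stem}")
            )
    return records


def filter_single_mask(records) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Keep cases with exactly one mask; multi-mask (or maskless) cases are
    excluded because they require multiple segmentation targets."""
    kept = [r for r in records if r.n_masks == 1]
    excluded = [r for r in records if r.n_masks != 1]
    logger.info("filter_single_mask: kept %d, excluded %d", len(kept), len(excluded))
    return kept, excluded


def split_sizes(n: int, fractions=(0.6, 0.2, 0.2)) -> tuple[int, int, int]:
    """Deterministic size rule: round(f_train*n) train, remainder split
    evenly between val and test, odd leftover to val."""
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_train = round(fractions[0] * n)
    rest = n - n_train
    n_test = rest // 2
    n_val = rest - n_test  # odd remainder goes to validation
    return n_train, n_val, n_test


def split_cases(records, spec: SplitSpec = SplitSpec()):
    """Shuffle by ``spec.seed`` and cut into (train, val, test) lists."""
    records = list(records)
    n_train, n_val, n_test = split_sizes(len(records), spec.fractions)
    order = np.random.default_rng(spec.seed).permutation(len(records))
    shuffled = [records[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def save_split_manifests(splits, out_dir) -> None:
    """Write train/val/test manifests as CSV (one row per case)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, records in zip(("train", "val", "test"), splits):
        pd.DataFrame(
            {
                "case_id": [r.case_id for r in records],
                "class": [r.class_label for r in records],
                "image_path": [str(r.image_path) for r in records],
                "mask_path": [str(r.mask_paths[0]) if r.mask_paths else "" for r in records],
            }
        ).to_csv(out_dir / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# pixel-level preprocessing
# ---------------------------------------------------------------------------

def load_pair(record: CaseRecord) -> tuple[np.ndarray, np.ndarray]:
    """Load (image, mask) as float32 [0,1] / uint8 {0,1} arrays.

    RGB PNGs are converted to single-channel luminance (ultrasound is
    grayscale); masks binarize at half intensity.
    """
    image = np.asarray(Image.open(record.image_path).convert("L"), dtype=np.float32) / 255.0
    mask = (np.asarray(Image.open(record.mask_paths[0]).convert("L")) > 127).astype(np.uint8)
    return image, mask


def pad_to_square(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pad with black to S x S (S = longer side), content anchored top-left."""
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    h, w = image.shape
    s = max(h, w)
    if h == w:
        return image, mask
    pimg = np.zeros((s, s), dtype=image.dtype)
    pmask = np.zeros((s, s), dtype=mask.dtype)
    pimg[:h, :w] = image
    pmask[:h, :w] = mask
    return pimg, pmask


def resize_pair(image: np.ndarray, mask: np.ndarray, target_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear resize for the image, nearest-neighbor for the mask."""
    if image.shape[0] != image.shape[1]:
        raise ValueError("resize_pair expects square inputs (pad first)")
    out_shape = (target_size, target_size)
    rimg = _sk_resize(image, out_shape, order=1, anti_aliasing=False, preserve_range=True).astype(np.float32)
    rmask = _sk_resize(mask, out_shape, order=0, anti_aliasing=False, preserve_range=True)
    return rimg, (rmask > 0.5).astype(np.uint8)


def normalize_image(image: np.ndarray, config: PreprocConfig) -> np.ndarray:
    return ((image - config.norm_mean) / config.norm_std).astype(np.float32)


def augment_pair(image: np.ndarray, mask: np.ndarray, config: PreprocConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Identical geometric transform on image and mask; rotation fills with
    black; normalization touches only the image."""
    if config.hflip and rng.uniform() < 0.5:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if config.rotation_degrees > 0:
        angle = float(rng.uniform(-config.rotation_degrees, config.rotation_degrees))
        if angle != 0.0:
            image = ndimage.rotate(image, angle, reshape=False, order=1, cval=0.0, prefilter=False)
            mask_f = ndimage.rotate(mask.astype(np.float32), angle, reshape=False, order=0, cval=0.0, prefilter=False)
            mask = (mask_f > 0.5).astype(np.uint8)
    if config.normalize:
        image = normalize_image(image, config)
    return image.astype(np.float32), mask


def preprocess_case(record: CaseRecord, config: PreprocConfig = PreprocConfig(),
                    rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: load -> pad -> resize -> (augment or just normalize)."""
    image, mask = load_pair(record)
    image, mask = pad_to_square(image, mask)
    image, mask = resize_pair(image, mask, config.target_size)
    if rng is not None:
        return augment_pair(image, mask, config, rng)
    if config.normalize:
        image = normalize_image(image, config)
    return image, mask
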