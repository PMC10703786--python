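"""Synthetic ultrasound-like phantoms with known lesion masks.

Each phantom is a speckle-textured grayscale image containing a single
darker lesion with an irregular, optionally blur-softened boundary, and
(optionally) a posterior acoustic shadow band below the lesion — the
artifacts that make real breast ultrasound hard to segment. The
generator is fully deterministic in (params, index): the per-phantom RNG
stream is spawned from a :class:`numpy.random.SeedSequence`.

The construction, in order:

1. lesion shape: an ellipse whose radius is modulated by a random
   low-order harmonic series (orders 2-5, amplitude =
   ``boundary_irregularity``), rescaled so the enclosed polygon area
   matches the sampled area fraction, then rasterized at pixel centers;
2. background: constant base intensity times low-frequency inhomogeneity
   and multiplicative speckle, both scaled by ``speckle_strength`` (so a
   strength of 0 gives an exactly constant background);
3. lesion darkening: subtract the sampled contrast inside the (possibly
   Gaussian-blurred) lesion indicator;
4. shadow: with probability ``shadow_prob``, darken the columns below
   the lesion with a linear falloff.

This is texture-level mimicry only — there is no beamforming or RF
physics — so conclusions from phantoms transfer to real ultrasound only
at the level of geometry and contrast, not acoustics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "generate_dataset",
    "worst_case_fixtures",
    "lesion_polygon",
    "polygon_area",
]

_N_THETA = 720  # boundary sampling for area normalization and rasterization


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration; all fractional quantities live in [0, 1]."""

    image_size: int = 224
    lesion_area_frac: tuple[float, float] = (0.02, 0.25)
    contrast: tuple[float, float] = (0.15, 0.5)
    edge_blur_sigma: tuple[float, float] = (1.0, 4.0)
    speckle_strength: tuple[float, float] = (0.2, 0.5)
    shadow_prob: float = 0.3
    boundary_irregularity: tuple[float, float] = (0.0, 0.3)
    seed: int = 0
    background_level: float = 0.6

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for name in ("lesion_area_frac", "contrast", "edge_blur_sigma", "speckle_strength", "boundary_irregularity"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty: ({lo}, {hi})")
            if lo < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.lesion_area_frac
        if hi > 1.0:
            raise ValueError("lesion_area_frac must lie within [0, 1]")
        if not 0.0 <= self.shadow_prob <= 1.0:
            raise ValueError("shadow_prob must lie in [0, 1]")
        if not 0.0 < self.background_level <= 1.0:
            raise ValueError("background_level must lie in (0, 1]")


def _rng_for(params: PhantomParams, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((params.seed, index)))


def _uniform(rng, bounds):
    lo, hi = bounds
    return lo if lo == hi else float(rng.uniform(lo, hi))


def lesion_polygon(params: PhantomParams, rng: np.random.Generator):
    """Sample the lesion boundary polygon: center, per-angle radii, vertices.

    The radius is ``r0 * (1 + sum_k a_k cos(k theta + phi_k))`` for
    harmonic orders k in 2..5, rescaled so the polygon area equals the
    sampled target area (fraction of the image). Returns
    ``(cy, cx, theta, radius, aspect)``.
    """
    s = params.image_size
    area_frac = _uniform(rng, params.lesion_area_frac)
    target_area = area_frac * s * s
    irregularity = _uniform(rng, params.boundary_irregularity)

    # center kept far enough from the border that the lesion stays inside
    margin = 0.5 * np.sqrt(target_area / np.pi) * (1.0 + irregularity) * 1.2
    margin = min(margin, s / 2 - 1)
    cy = float(rng.uniform(margin, s - margin))
    cx = float(rng.uniform(margin, s - margin))

    theta = np.linspace(0.0, 2 * np.pi, _N_THETA, endpoint=False)
    aspect = float(rng.uniform(0.6, 1.0))  # ellipse axis ratio
    base = 1.0 / np.sqrt(np.cos(theta) ** 2 / aspect + np.sin(theta) ** 2 * aspect)

    mod = np.zeros_like(theta)
    if irregularity > 0:
        orders = np.arange(2, 6)
        amps = rng.uniform(0.0, 1.0, size=orders.size)
        amps *= irregularity / max(amps.sum(), 1e-12)
        phases = rng.uniform(0.0, 2 * np.pi, size=orders.size)
        for k, a, ph in zip(orders, amps, phases):
            mod += a * np.cos(k * theta + ph)
    radius = base * (1.0 + mod)
    radius = np.maximum(radius, 0.05 * radius.max())

    # rescale so the polygon encloses exactly the target area
    ys = radius * np.sin(theta)
    xs = radius * np.cos(theta)
    area = polygon_area(xs, ys)
    radius *= np.sqrt(target_area / area)
    return cy, cx, theta, radius, aspect


def polygon_area(xs: np.ndarray, ys: np.ndarray) -> float:
    """Shoelace area of a closed polygon given its vertices in order."""
    return float(0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))))


def _rasterize(params: PhantomParams, cy, cx, theta, radius) -> np.ndarray:
    """Pixel-center inside test against the star-convex boundary r(theta)."""
    s = params.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    dy = yy - cy
    dx = xx - cx
    ang = np.arctan2(dy, dx) % (2 * np.pi)
    idx = np.clip((ang / (2 * np.pi) * _N_THETA).astype(int), 0, _N_THETA - 1)
    rr = np.hypot(dy, dx)
    return (rr <= radius[idx]).astype(np.uint8)


def generate_phantom(params: PhantomParams, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair, both ``image_size`` square float/uint8.

    Returns ``image`` as float32 in [0, 1] and ``mask`` as uint8 in {0, 1}.
    The lesion is a single 8-connected component whose area lies in the
    configured fraction range, and its mean intensity sits below the
    background mean by the sampled contrast before edge blurring.
    """
    rng = _rng_for(params, index)
    s = params.image_size

    for _ in range(8):  # reject the rare disconnected rasterization
        cy, cx, theta, radius, _ = lesion_polygon(params, rng)
        mask = _rasterize(params, cy, cx, theta, radius)
        n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
        if n_comp == 1:
            break

    contrast = _uniform(rng, params.contrast)
    blur = _uniform(rng, params.edge_blur_sigma)
    speckle = _uniform(rng, params.speckle_strength)

    b0 = params.background_level
    background = np.full((s, s), b0, dtype=np.float64)
    if speckle > 0:
        lowfreq = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=s / 8)
        lowfreq /= max(np.abs(lowfreq).max(), 1e-12)
        background *= 1.0 + 0.5 * speckle * lowfreq
        background *= 1.0 + speckle * rng.standard_normal((s, s))

    indicator = mask.astype(np.float64)
    if blur > 0:
        indicator = ndimage.gaussian_filter(indicator, sigma=blur)
    image = background - contrast * indicator

    if rng.uniform() < params.shadow_prob:
        image = _apply_shadow(image, mask, rng)

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return image, mask


def _apply_shadow(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Darken the columns below the lesion with a linear falloff."""
    cols = np.where(mask.any(axis=0))[0]
    if cols.size == 0:
        return image
    bottom = np.where(mask.any(axis=1))[0].max()
    s = image.shape[0]
    if bottom + 1 >= s:
        return image
    strength = float(rng.uniform(0.2, 0.5))
    depth = np.arange(s - bottom - 1, dtype=np.float64)
    falloff = strength * np.maximum(1.0 - depth / max(s - bottom - 1, 1), 0.0)
    shade = np.ones_like(image)
    shade[bottom + 1:, cols[0]:cols[-1] + 1] -= falloff[:, None]
    return image * shade


def generate_dataset(params: PhantomParams, n: int, out_dir) -> "pd.DataFrame":
    """Write n phantom pairs as 8-bit PNGs in the BUSI naming convention.

    Files are ``phantom (k).png`` / ``phantom (k)_mask.png`` (k = 1..n)
    under ``out_dir/phantom/``, plus a ``manifest.csv`` with one row per
    case (filename, class, lesion area in pixels).
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    class_dir = out_dir / "phantom"
    class_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for k in range(1, n + 1):
        image, mask = generate_phantom(params, k)
        img_name = f"phantom ({k}).png"
        mask_name = f"phantom ({k})_mask.png"
        Image.fromarray(np.round(image * 255).astype(np.uint8), mode="L").save(class_dir / img_name)
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(class_dir / mask_name)
        rows.append({"filename": f"phantom/{img_name}", "class": "phantom", "area": int(mask.sum())})

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def worst_case_fixtures(image_size: int = 64) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Edge-case (image, mask) pairs every consumer must survive:
    empty mask (normal tissue), full-frame mask, a single pixel, and a
    lesion touching the image border."""
    s = image_size
    rng = np.random.default_rng(1234)
    texture = np.clip(0.6 * (1.0 + 0.3 * rng.standard_normal((s, s))), 0, 1).astype(np.float32)

    empty = np.zeros((s, s), dtype=np.uint8)
    full = np.ones((s, s), dtype=np.uint8)
    one_px = np.zeros((s, s), dtype=np.uint8)
    one_px[s // 2, s // 2] = 1
    border = np.zeros((s, s), dtype=np.uint8)
    border[0 : s // 4, s // 3 : 2 * s // 3] = 1

    def with_lesion(mask):
        return np.clip(texture - 0.3 * mask, 0, 1).astype(np.float32)

    return {
        "empty": (texture.copy(), empty),
        "full": (np.clip(texture - 0.3, 0, 1).astype(np.float32), full),
        "one_pixel": (with_lesion(one_px), one_px),
        "border": (with_lesion(border), border),
    }
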