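"""Seeded brain-phantom generator and on-disk slice-dataset I/O.

The phantom emulates the qualitative challenges of 2-D tumor slices without
claiming anatomical realism: a smooth elliptical "brain" intensity field
with low-frequency texture and additive Gaussian noise, and (with a
configurable probability) a lesion built from a base ellipse plus small
protruding lobes — the irregular, crab-foot-like boundary shapes that make
real tumor outlines hard to segment.  The lesion is rendered brighter than
the surrounding tissue and its exact binary mask is returned alongside.

Datasets are written as 8-bit PNG pairs (image, 0/255 mask) with a JSON
manifest recording a seeded train/test split, and read back resized to a
uniform 256x256 (bilinear for images, nearest + re-binarization for masks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = ["PhantomConfig", "generate_phantom", "make_dataset", "load_pairs"]

MASK_SUFFIX = "_mask"


@dataclass(frozen=True)
class PhantomConfig:
    size: int = 256
    lesion_probability: float = 0.9
    n_lobes: tuple[int, int] = (2, 5)
    lesion_area_fraction: tuple[float, float] = (0.01, 0.12)
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo < hi < 0.5):
            raise ValueError("lesion_area_fraction must satisfy 0 < lo < hi < 0.5")
        if self.size % 32:
            raise ValueError("size must be divisible by 32")
        if not (0.0 <= self.lesion_probability <= 1.0):
            raise ValueError("lesion_probability must lie in [0, 1]")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    yv, xv = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xv + st * yv
    v = -st * xv + ct * yv
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _lesion_mask(rng: np.random.Generator, cfg: PhantomConfig,
                 brain: np.ndarray) -> np.ndarray:
    """Base ellipse + protruding lobes; rejection-resampled into the target
    area-fraction band (fraction of the whole image)."""
    size = cfg.size
    lo, hi = cfg.lesion_area_fraction
    target = rng.uniform(lo, hi)
    cy = rng.uniform(0.3, 0.7) * size
    cx = rng.uniform(0.3, 0.7) * size
    aspect = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0, np.pi)
    n_lobes = int(rng.integers(cfg.n_lobes[0], cfg.n_lobes[1] + 1))
    lobe_angles = rng.uniform(0, 2 * np.pi, size=n_lobes)
    lobe_scales = rng.uniform(0.3, 0.55, size=n_lobes)
    lobe_aspects = rng.uniform(0.5, 1.0, size=n_lobes)

    # initial base radius from the target area, then multiplicative correction
    r = np.sqrt(target * size * size / (np.pi * aspect))
    for _ in range(60):
        ry, rx = r * aspect, r
        mask = _ellipse_mask(size, cy, cx, ry, rx, theta)
        for ang, sc, asp in zip(lobe_angles, lobe_scales, lobe_aspects):
            ly = cy + ry * np.sin(ang)
            lx = cx + rx * np.cos(ang)
            mask |= _ellipse_mask(size, ly, lx, sc * ry * asp, sc * rx, ang)
        mask &= brain
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
        if frac <= 0:
            r *= 1.3
            continue
        r *= np.sqrt(((lo + hi) / 2) / frac)
    raise RuntimeError("lesion area fraction did not converge")


def generate_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (image (3, S, S) float64 in [0,1], mask (1, S, S) float 0/1)."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ry = rng.uniform(0.36, 0.44) * size
    rx = rng.uniform(0.30, 0.40) * size
    theta = rng.uniform(-0.3, 0.3)
    brain = _ellipse_mask(size, cy, cx, ry, rx, theta)

    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    img = np.zeros((size, size), dtype=np.float64)
    img[brain] = 0.35 + 0.25 * (1.0 - r2[brain])
    texture = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 16)
    tex_rng = np.ptp(texture)
    if tex_rng > 0:
        img[brain] += 0.10 * ((texture - texture.min()) / tex_rng - 0.5)[brain]

    if rng.uniform() < cfg.lesion_probability:
        mask = _lesion_mask(rng, cfg, brain)
    else:
        mask = np.zeros((size, size), dtype=bool)

    if mask.any():
        soft = gaussian_filter(mask.astype(np.float64), sigma=1.0)
        img += 0.35 * soft                          # lesion renders brighter

    img += rng.normal(0.0, cfg.noise_sigma, (size, size))
    img = np.clip(img, 0.0, 1.0)
    image = np.repeat(img[None], 3, axis=0)
    return image, mask[None].astype(np.float64)


def make_dataset(cfg: PhantomConfig, n: int, out_dir,
                 split_ratio: float = 0.8) -> dict:
    """Write n seeded phantom pairs as PNG and a manifest with the split."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(n):
        item_cfg = PhantomConfig(**{**cfg.__dict__, "seed": cfg.seed + 1 + i})
        image, mask = generate_phantom(item_cfg)
        stem = f"phantom_{i:04d}"
        img8 = np.round(image[0] * 255).astype(np.uint8)
        msk8 = (mask[0] > 0.5).astype(np.uint8) * 255
        iio.imwrite(out / f"{stem}.png", img8)
        iio.imwrite(out / f"{stem}{MASK_SUFFIX}.png", msk8)
        pairs.append({"image": f"{stem}.png", "mask": f"{stem}{MASK_SUFFIX}.png"})

    order = np.random.default_rng(cfg.seed).permutation(n)
    n_train = int(round(split_ratio * n))
    train = sorted(int(i) for i in order[:n_train])
    test = sorted(int(i) for i in order[n_train:])
    manifest = {
        "seed": cfg.seed, "size": cfg.size, "n": n,
        "split_ratio": split_ratio,
        "pairs": pairs, "train": train, "test": test,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _find_pairs(directory: Path) -> list[tuple[str, Path, Path]]:
    exts = (".png", ".tif", ".tiff")
    images = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in exts and not p.stem.endswith(MASK_SUFFIX))
    out = []
    for img in images:
        mask = None
        for ext in exts:
            cand = directory / f"{img.stem}{MASK_SUFFIX}{ext}"
            if cand.exists():
                mask = cand
                break
        if mask is None:
            raise FileNotFoundError(
                f"no mask found for image stem '{img.stem}' "
                f"(expected '{img.stem}{MASK_SUFFIX}.<ext>')")
        out.append((img.stem, img, mask))
    return out


def load_pairs(directory, target_size: int = 256):
    """Load (images (N,3,S,S), masks (N,1,S,S), stems) from a slice folder.

    Images are bilinearly resized to ``target_size`` and scaled to [0, 1];
    masks are nearest-neighbour resized and re-binarized at 0.5.
    """
    directory = Path(directory)
    found = _find_pairs(directory)
    if not found:
        raise FileNotFoundError(f"no image/mask pairs in {directory}")
    images, masks, stems = [], [], []
    for stem, img_path, mask_path in found:
        img = np.asarray(iio.imread(img_path), dtype=np.float64) / 255.0
        if img.ndim == 2:
            img = np.repeat(img[None], 3, axis=0)
        else:
            img = img[..., :3].transpose(2, 0, 1)
        if img.shape[1] != target_size or img.shape[2] != target_size:
            img = np.stack([
                resize(ch, (target_size, target_size), order=1,
                       preserve_range=True, anti_aliasing=False)
                for ch in img])
        msk = np.asarray(iio.imread(mask_path), dtype=np.float64) / 255.0
        if msk.ndim == 3:
            msk = msk[..., 0]
        if msk.shape != (target_size, target_size):
            msk = resize(msk, (target_size, target_size), order=0,
                         preserve_range=True, anti_aliasing=False)
        msk = (msk >= 0.5).astype(np.float64)
        images.append(img)
        masks.append(msk[None])
        stems.append(stem)
    return np.stack(images), np.stack(masks), stems
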