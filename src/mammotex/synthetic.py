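"""Synthetic mammogram-like texture generator.

Real fatty, glandular and dense breast tissue differ both in overall
radiodensity and in texture: fatty regions are dark and smooth, glandular
tissue shows a mixture of mid-intensity blobs and strands, and dense
tissue is bright with coarse, strongly oriented fibrous structure.  The
generator emulates this with a parametric model: a base intensity level,
Gaussian blobs at Poisson-distributed locations, oriented line segments
whose directions follow a von Mises distribution (controlling
anisotropy), and additive Gaussian noise, clipped to the 8-bit range.

The class presets (F/G/D) separate along blob density, streak anisotropy
and noise level as well as base intensity, so they exercise both the
orientation-sensitive and the intensity-invariant aspects of the texture
descriptors.  ``effect`` scales every class difference toward a common
midpoint: ``effect=1`` gives the full presets, ``effect=0`` collapses all
three classes onto identical parameters (a chance-level control).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import line_aa

from .roi import write_pgm, write_labels

__all__ = ["TextureRecipe", "PRESETS", "recipe_for", "generate_texture",
           "generate_arrays", "generate_dataset"]


@dataclass(frozen=True)
class TextureRecipe:
    """Parameters of one synthetic tissue image.

    Rates are expressed per 1000 pixels of image area; lengths and radii
    in pixels; intensities in 8-bit grey levels.
    """

    label: str
    base: float
    blob_rate: float
    blob_radius: tuple[float, float]
    blob_amp: float
    streak_rate: float
    streak_kappa: float
    streak_mu: float
    streak_len: tuple[float, float]
    streak_amp: float
    noise_sigma: float
    seed: int = 0


# Class presets: fatty = dark/smooth, glandular = mixed blobs + weak
# strands, dense = bright/coarse with strongly oriented fibres.
PRESETS: dict[str, dict] = {
    "F": dict(base=70.0, blob_rate=0.25, blob_radius=(2.0, 4.0), blob_amp=18.0,
              streak_rate=0.0, streak_kappa=2.0, streak_mu=30.0,
              streak_len=(10.0, 25.0), streak_amp=0.0, noise_sigma=2.5),
    "G": dict(base=115.0, blob_rate=1.2, blob_radius=(2.0, 6.0), blob_amp=30.0,
              streak_rate=0.5, streak_kappa=2.0, streak_mu=30.0,
              streak_len=(10.0, 30.0), streak_amp=28.0, noise_sigma=5.0),
    "D": dict(base=170.0, blob_rate=3.5, blob_radius=(3.0, 8.0), blob_amp=40.0,
              streak_rate=1.5, streak_kappa=6.0, streak_mu=30.0,
              streak_len=(15.0, 40.0), streak_amp=45.0, noise_sigma=8.0),
}


def _lerp(a, b, t: float):
    if isinstance(a, tuple):
        return tuple(x + t * (y - x) for x, y in zip(a, b))
    return a + t * (b - a)


def recipe_for(label: str, seed: int = 0, effect: float = 1.0) -> TextureRecipe:
    """Preset recipe for a class, with class differences scaled by
    ``effect`` toward the glandular midpoint (0 = all classes identical)."""
    if label not in PRESETS:
        raise ValueError(f"unknown class label {label!r}; expected one of F, G, D")
    mid, tgt = PRESETS["G"], PRESETS[label]
    params = {k: _lerp(mid[k], tgt[k], effect) for k in tgt}
    return TextureRecipe(label=label, seed=seed, **params)


def generate_texture(recipe: TextureRecipe, size: int = 128) -> np.ndarray:
    """Render one synthetic tissue image (uint8, ``size`` x ``size``)."""
    if recipe.label not in PRESETS:
        raise ValueError(f"unknown class label {recipe.label!r}")
    if size < 64:
        raise ValueError("size must be at least 64")
    rng = np.random.default_rng(recipe.seed)
    img = np.full((size, size), float(recipe.base))
    area_k = size * size / 1000.0

    n_blobs = rng.poisson(recipe.blob_rate * area_k)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(*recipe.blob_radius)
        amp = recipe.blob_amp * rng.uniform(0.6, 1.4)
        sigma = max(r / 2.0, 0.5)
        ylo, yhi = max(0, int(cy - 3 * sigma)), min(size, int(cy + 3 * sigma) + 1)
        xlo, xhi = max(0, int(cx - 3 * sigma)), min(size, int(cx + 3 * sigma) + 1)
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        img[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )

    n_streaks = rng.poisson(recipe.streak_rate * area_k)
    for _ in range(n_streaks):
        ang = rng.vonmises(np.deg2rad(recipe.streak_mu), recipe.streak_kappa)
        cy, cx = rng.uniform(0, size, 2)
        half = rng.uniform(*recipe.streak_len) / 2.0
        dy, dx = -half * np.sin(ang), half * np.cos(ang)
        r0 = int(np.clip(cy - dy, 0, size - 1))
        c0 = int(np.clip(cx - dx, 0, size - 1))
        r1 = int(np.clip(cy + dy, 0, size - 1))
        c1 = int(np.clip(cx + dx, 0, size - 1))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] += recipe.streak_amp * rng.uniform(0.7, 1.3) * val

    if recipe.noise_sigma > 0:
        img += rng.normal(0.0, recipe.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _image_seed(seed: int, idx: int) -> int:
    return (seed * 1_000_003 + idx) % (2**31 - 1)


def generate_arrays(
    n_per_class: int, size: int = 128, seed: int = 0, effect: float = 1.0
) -> tuple[list[str], list[str], list[np.ndarray]]:
    """In-memory dataset: (image ids, class labels, images)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ids, labels, images = [], [], []
    idx = 0
    for label in ("F", "G", "D"):
        for _ in range(n_per_class):
            recipe = recipe_for(label, seed=_image_seed(seed, idx), effect=effect)
            ids.append(f"mdb{idx + 1:03d}")
            labels.append(label)
            images.append(generate_texture(recipe, size))
            idx += 1
    return ids, labels, images


def generate_dataset(
    out_dir: str | os.PathLike,
    n_per_class: int = 40,
    size: int = 128,
    seed: int = 0,
    effect: float = 1.0,
) -> pd.DataFrame:
    """Write a labelled synthetic dataset: PGM images plus ``labels.csv``.

    Returns the label table (``image_id``, ``class``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids, labels, images = generate_arrays(n_per_class, size, seed, effect)
    for iid, img in zip(ids, images):
        write_pgm(out / f"{iid}.pgm", img)
    write_labels(out / "labels.csv", list(zip(ids, labels)))
    return pd.DataFrame({"image_id": ids, "class": labels})
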