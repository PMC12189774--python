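"""Seeded synthetic histopathology-like tiles with ground-truth masks.

Generates three separable texture regimes loosely inspired by the
morphology of the Ph-negative myeloproliferative neoplasm subtypes —
many small fine-grained nuclei (PV-like increased erythropoiesis),
clustered large smooth nuclei (ET-like megakaryocyte clustering), and
coarse-textured nuclei over a streaky fibrous background (MF-like
reticulin fibrosis). The recipes are purely phenomenological knobs on
granularity, intensity, size, and spatial clustering; they are never
claimed to be biologically faithful. Their purpose is to give every
pipeline stage a ground truth: exact nucleus label masks, known class
structure, and tunable class separation.

All randomness flows from a single seed through per-tile child seeds
drawn once from the master generator, so any tile can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .segmentation import LabelMask

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class ClassRecipe:
    """Texture regime for one class.

    Units: radii and grain in pixels; intensities in [0, 1] gray;
    ``clustering`` in [0, 1] interpolates uniform placement (0) to
    aggregation around a few cluster centers (1). ``grain`` is the
    correlation length (Gaussian smoothing sigma) of the within-nucleus
    noise. ``bg_sigma`` gives the background smoothing per axis; an
    anisotropic pair produces the streaky fibrous look.
    """

    name: str
    n_nuclei: tuple[int, int] = (8, 14)
    radius: tuple[float, float] = (5.0, 9.0)
    intensity_mean: float = 0.35
    intensity_sd: float = 0.08
    grain: float = 1.0
    clustering: float = 0.3
    bg_mean: float = 0.85
    bg_amplitude: float = 0.04
    bg_sigma: tuple[float, float] = (8.0, 8.0)

    def __post_init__(self) -> None:
        if self.n_nuclei[0] > self.n_nuclei[1] or self.radius[0] > self.radius[1]:
            raise ValueError("ranges must be non-degenerate (lo <= hi)")
        if self.grain <= 0:
            raise ValueError("grain must be > 0")
        if not (0 <= self.clustering <= 1):
            raise ValueError("clustering must lie in [0, 1]")


def default_recipes() -> tuple[ClassRecipe, ClassRecipe, ClassRecipe]:
    """The three default separable regimes (PV-like, ET-like, MF-like)."""
    return (
        ClassRecipe(name="PV", n_nuclei=(12, 18), radius=(4.0, 7.0),
                    intensity_mean=0.30, intensity_sd=0.09, grain=0.7,
                    clustering=0.15, bg_sigma=(8.0, 8.0)),
        ClassRecipe(name="ET", n_nuclei=(5, 8), radius=(9.0, 13.0),
                    intensity_mean=0.45, intensity_sd=0.05, grain=2.5,
                    clustering=0.85, bg_sigma=(8.0, 8.0)),
        ClassRecipe(name="MF", n_nuclei=(8, 12), radius=(6.0, 9.0),
                    intensity_mean=0.38, intensity_sd=0.13, grain=1.5,
                    clustering=0.4, bg_sigma=(2.0, 16.0)),
    )


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: tuple[float, float]) -> np.ndarray:
    """Zero-mean, unit-sd correlated Gaussian field."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _place_centers(rng: np.random.Generator, n: int, side: int,
                   margin: float, clustering: float) -> list[tuple[float, float]]:
    """Clustered point process: uniform draws vs draws around cluster
    centers, mixed by the clustering parameter."""
    n_centers = max(1, n // 4)
    hubs = rng.uniform(margin, side - margin, size=(n_centers, 2))
    spread = margin * 1.5
    pts = []
    for _ in range(n):
        if rng.uniform() < clustering:
            hub = hubs[rng.integers(n_centers)]
            p = rng.normal(hub, spread)
            p = np.clip(p, margin, side - margin)
        else:
            p = rng.uniform(margin, side - margin, size=2)
        pts.append((float(p[0]), float(p[1])))
    return pts


def generate_tile(recipe: ClassRecipe, side: int = 256,
                  seed: int = 0) -> tuple[np.ndarray, LabelMask]:
    """Render one RGB tile and its exact nucleus label mask.

    Elliptical nuclei (random radii within the recipe range, random
    orientation) are placed by the clustered point process with
    rejection against overlap; each is filled with correlated noise of
    the recipe's grain around its intensity mean. Deterministic per
    (recipe, side, seed). Raises after bounded retries if the requested
    nuclei cannot be packed.
    """
    if side < 64:
        raise ValueError("side must be >= 64")
    rng = np.random.default_rng(seed)
    bg = recipe.bg_mean + recipe.bg_amplitude * _smooth_noise(
        rng, (side, side), recipe.bg_sigma)
    gray = np.clip(bg, 0.0, 1.0)

    n = int(rng.integers(recipe.n_nuclei[0], recipe.n_nuclei[1] + 1))
    labels = np.zeros((side, side), dtype=np.int32)
    rows, cols = np.mgrid[0:side, 0:side]
    margin = recipe.radius[1] + 2
    placed = 0
    attempts = 0
    max_attempts = 400 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"infeasible packing: placed {placed}/{n} nuclei for recipe "
                f"{recipe.name!r} after {max_attempts} attempts")
        attempts += 1
        cy, cx = _place_centers(rng, 1, side, margin, recipe.clustering)[0]
        a = rng.uniform(*recipe.radius)
        b = rng.uniform(*recipe.radius)
        phi = rng.uniform(0, np.pi)
        dy, dx = rows - cy, cols - cx
        u = dy * np.cos(phi) + dx * np.sin(phi)
        v = -dy * np.sin(phi) + dx * np.cos(phi)
        ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # reject overlaps (1-px moat keeps nuclei 4-disconnected)
        moat = ndimage.binary_dilation(ellipse)
        if (labels[moat] != 0).any():
            continue
        placed += 1
        labels[ellipse] = placed
        texture = recipe.intensity_mean + recipe.intensity_sd * _smooth_noise(
            rng, (side, side), (recipe.grain, recipe.grain))
        gray[ellipse] = np.clip(texture[ellipse], 0.0, 1.0)

    # near-gray tint: nuclei lean blue-purple, background pink
    r = np.clip(gray * 1.02, 0, 1)
    g = np.clip(gray * 0.92, 0, 1)
    b_ = np.clip(gray * 1.05, 0, 1)
    rgb = (np.stack([r, g, b_], axis=-1) * 255).round().astype(np.uint8)
    return rgb, LabelMask.from_labels(labels)


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Per-tile child seeds derived once from the master seed."""
    return np.random.default_rng(seed).integers(0, MAX_SEED, size=n)


def generate_dataset_arrays(
    recipes: Sequence[ClassRecipe] | None = None,
    n_per_class: int = 100, side: int = 256, seed: int = 0,
) -> list[dict]:
    """In-memory dataset: one record per tile.

    Records carry ``sample_id``, ``label``, ``pixels`` (uint8 RGB),
    ``mask`` (:class:`LabelMask`), and the child ``seed`` used.
    """
    recipes = tuple(recipes) if recipes is not None else default_recipes()
    if len({r.name for r in recipes}) != len(recipes):
        raise ValueError("recipes must have distinct names")
    seeds = child_seeds(seed, len(recipes) * n_per_class)
    records = []
    k = 0
    for recipe in recipes:
        for i in range(n_per_class):
            s = int(seeds[k]); k += 1
            rgb, mask = generate_tile(recipe, side=side, seed=s)
            records.append({"sample_id": f"{recipe.name}_{i:04d}",
                            "label": recipe.name, "pixels": rgb,
                            "mask": mask, "seed": s})
    return records


def generate_dataset(out_dir: str | Path,
                     recipes: Sequence[ClassRecipe] | None = None,
                     n_per_class: int = 100, side: int = 256,
                     seed: int = 0) -> Path:
    """Write a directory-per-class dataset with masks and a manifest.

    Layout mirrors the real dataset: ``out/<class>/<id>.png`` plus
    ``<id>_mask.png`` (16-bit) and ``manifest.csv`` recording child seeds.
    """
    import csv

    from PIL import Image

    from .segmentation import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_dataset_arrays(recipes, n_per_class, side, seed)
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "label", "seed", "image", "mask"])
        for rec in records:
            cls_dir = out / rec["label"]
            cls_dir.mkdir(exist_ok=True)
            img_path = cls_dir / f"{rec['sample_id']}.png"
            mask_path = cls_dir / f"{rec['sample_id']}_mask.png"
            Image.fromarray(rec["pixels"]).save(img_path)
            write_mask(rec["mask"], mask_path)
            w.writerow([rec["sample_id"], rec["label"], rec["seed"],
                        img_path.relative_to(out), mask_path.relative_to(out)])
    return out
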