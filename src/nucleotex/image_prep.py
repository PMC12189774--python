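"""Image loading, color conversion, normalization, and tiling.

Every downstream stage (segmentation, texture features, embeddings) consumes
the rasters produced here. RGB input images are converted to the CIE XYZ
color space (device-independent; the Y channel is a perceptual luminance
scalar used for segmentation and texture analysis), then percentile-
normalized per channel.

Coordinate convention: 0-based (row, col), half-open extents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

# sRGB (D65) -> CIE XYZ matrix, applied after gamma expansion.
# Rows map to X, Y, Z; the Y row sums to 1 so white -> Y = 1.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: default percentile bounds for :func:`percentile_normalize`
DEFAULT_PERCENTILES = (1.0, 99.8)


@dataclass
class RawImage:
    """8-bit RGB raster with optional class label.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
    source_id : opaque identifier (usually the file stem)
    class_label : one of ``{"ET", "PV", "MF"}`` or ``None``
    """

    pixels: np.ndarray
    source_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"RawImage requires an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RawImage must have H >= 1 and W >= 1")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class NormalizedImage:
    """Floating raster in [0, 1] plus the per-channel bounds used."""

    pixels: np.ndarray
    normalization_record: list[tuple[float, float]] = field(default_factory=list)
    source_id: str = ""
    class_label: str | None = None

    @property
    def luminance(self) -> np.ndarray:
        """Scalar channel for segmentation / texture (Y of XYZ, or the
        single channel if already 2-D)."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels[..., 1]


@dataclass
class Tile:
    """Square sub-raster with its origin in the parent image."""

    pixels: np.ndarray
    origin: tuple[int, int]
    parent_id: str = ""

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def rgb_to_xyz(img: RawImage | np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB raster to linear CIE XYZ (D65).

    Gamma expansion follows the piecewise sRGB electro-optical transfer
    function; the linear RGB triple is then multiplied by the standard
    D65 matrix. Output Y lies in [0, 1]; X and Z reach the white-point
    values 0.9505 and 1.0890.
    """
    px = img.pixels if isinstance(img, RawImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected 3-channel input, got shape {px.shape}")
    srgb = px.astype(np.float64) / 255.0
    linear = np.where(
        srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4
    )
    return linear @ _SRGB_TO_XYZ.T


def percentile_normalize(
    img: np.ndarray,
    p_low: float = DEFAULT_PERCENTILES[0],
    p_high: float = DEFAULT_PERCENTILES[1],
) -> NormalizedImage:
    """Affine-rescale each channel so percentile ``p_low`` maps to 0 and
    ``p_high`` to 1, clipping to [0, 1].

    A constant channel (identical low/high percentile) is left all-zeros
    and a warning is logged — there is no meaningful contrast to stretch.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"require 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    arr = np.asarray(img, dtype=np.float64)
    single = arr.ndim == 2
    chans = arr[..., None] if single else arr
    out = np.zeros_like(chans)
    record: list[tuple[float, float]] = []
    for c in range(chans.shape[2]):
        lo = float(np.percentile(chans[..., c], p_low))
        hi = float(np.percentile(chans[..., c], p_high))
        record.append((lo, hi))
        if hi <= lo:
            logger.warning(
                "channel %d is constant at percentiles (%g, %g); left as zeros",
                c, p_low, p_high,
            )
            warnings.warn(
                f"channel {c} has zero percentile range; normalized to zeros",
                stacklevel=2,
            )
            continue
        out[..., c] = np.clip((chans[..., c] - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedImage(
        pixels=out[..., 0] if single else out, normalization_record=record
    )


def extract_tiles(
    img: NormalizedImage | np.ndarray,
    side: int = 256,
    stride: int | None = None,
    parent_id: str = "",
) -> list[Tile]:
    """Cut a row-major grid of ``side``-square tiles.

    Tiles whose footprint would cross the image edge are dropped; no
    padding is applied (padded pixels would fabricate tissue). With
    ``stride == side`` and image sides that are multiples of ``side`` the
    tiles partition the image exactly.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    stride = side if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(img, NormalizedImage):
        px = img.pixels
        parent_id = parent_id or img.source_id
    else:
        px = np.asarray(img)
    h, w = px.shape[:2]
    if h < side or w < side:
        warnings.warn(
            f"image ({h}x{w}) smaller than one {side}-pixel tile", stacklevel=2
        )
        return []
    tiles = []
    for r in range(0, h - side + 1, stride):
        for c in range(0, w - side + 1, stride):
            tiles.append(Tile(pixels=px[r : r + side, c : c + side], origin=(r, c),
                              parent_id=parent_id))
    return tiles


def resize_tile(t: Tile, target_side: int) -> Tile:
    """Bilinearly resample a tile to ``target_side`` square.

    Values are clipped to the input range so interpolation cannot
    overshoot the original min/max.
    """
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    from skimage.transform import resize

    px = t.pixels
    out_shape = (target_side, target_side) + px.shape[2:]
    lo, hi = float(px.min()), float(px.max())
    res = resize(px.astype(np.float64), out_shape, order=1, mode="edge",
                 anti_aliasing=False)
    res = np.clip(res, lo, hi)
    return Tile(pixels=res, origin=t.origin, parent_id=t.parent_id)


def load_image(path: str | Path, class_label: str | None = None) -> RawImage:
    """Read a PNG/TIFF/JPEG file into a :class:`RawImage`."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return RawImage(pixels=px, source_id=path.stem, class_label=class_label)


def iter_dataset(root: str | Path) -> Iterator[RawImage]:
    """Yield (image, label) records from a directory-per-class layout.

    ``root/<class>/<image>.{png,tif,tiff,jpg,jpeg}``; the class directory
    name becomes the label. Mask files (``*_mask.*``) are skipped.
    """
    root = Path(root)
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(class_dir.iterdir()):
            if f.suffix.lower() in exts and not f.stem.endswith("_mask"):
                yield load_image(f, class_label=class_dir.name)


def write_tile_manifest(tiles: Sequence[Tile], path: str | Path) -> None:
    """Serialize tile origins as CSV: parent_id, row, col, side."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parent_id", "row", "col", "side"])
        for t in tiles:
            w.writerow([t.parent_id, t.origin[0], t.origin[1], t.side])
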