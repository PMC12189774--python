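"""Nuclei segmentation: pluggable backends producing integer label masks.

Three backends satisfy the segmenter contract (normalized raster in,
same-shape integer label raster out):

* ``StarDistSegmenter`` — wraps a pretrained StarDist 2D model when the
  optional ``stardist`` package is installed; probability threshold 0.65
  and NMS threshold 0.1 are passed through by default.
* ``builtin_blob_segmenter`` — deterministic Otsu threshold + 4-connected
  components; lets the full pipeline run without external model weights.
* file-supplied masks read with :func:`read_mask`.

Label masks use 0 for background and contiguous ids 1..n for nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy import ndimage

from .image_prep import NormalizedImage

#: StarDist operating point used when the adapter is available
STARDIST_PROB_THRESHOLD = 0.65
STARDIST_NMS_THRESHOLD = 0.1

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


class SegmenterUnavailableError(RuntimeError):
    """Raised when an optional segmentation backend cannot be imported."""


@dataclass
class LabelMask:
    """Integer label raster: 0 = background, k >= 1 = nucleus id."""

    labels: np.ndarray
    n_regions: int

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMask":
        """Build a mask with ids compacted to the contiguous range 1..n."""
        labels = np.asarray(labels)
        if np.any(labels < 0):
            raise ValueError("label raster must be non-negative")
        ids = np.unique(labels)
        ids = ids[ids > 0]
        lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
        for new, old in enumerate(ids, start=1):
            lut[old] = new
        return cls(labels=lut[labels], n_regions=len(ids))


@dataclass
class RegionPatch:
    """Per-nucleus crop: gray values, boolean mask, and bookkeeping."""

    gray: np.ndarray
    mask: np.ndarray
    region_id: int
    area: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    def __post_init__(self) -> None:
        if self.gray.shape != self.mask.shape:
            raise ValueError("gray and mask shapes must agree")

    @property
    def masked_values(self) -> np.ndarray:
        return self.gray[self.mask]


def builtin_blob_segmenter(
    img: np.ndarray,
    threshold_rule: Callable[[np.ndarray], float] | None = None,
    foreground: Literal["bright", "dark", "auto"] = "auto",
) -> np.ndarray:
    """Global threshold (Otsu by default) + 4-connected component labels.

    ``foreground`` picks which side of the threshold is nuclei: ``auto``
    takes the minority side, which handles both bright blobs on dark
    background and the dark-nuclei-on-bright-tissue case of histopathology.
    Deterministic; degenerate (constant) images yield zero regions.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("builtin segmenter expects a single-channel raster")
    if arr.max() == arr.min():
        return np.zeros(arr.shape, dtype=np.int32)
    if threshold_rule is None:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(arr)
    else:
        thr = threshold_rule(arr)
    bright = arr > thr
    if foreground == "bright":
        fg = bright
    elif foreground == "dark":
        fg = ~bright
    else:
        fg = bright if bright.sum() <= (~bright).sum() else ~bright
    labels, _ = ndimage.label(fg, structure=_STRUCT_4)
    return labels.astype(np.int32)


class StarDistSegmenter:
    """Adapter around a pretrained StarDist 2D model (optional dependency).

    The network itself is an external artifact; this class only forwards
    the normalized raster and the published operating point.
    """

    def __init__(
        self,
        model_name: str = "2D_versatile_he",
        prob_thresh: float = STARDIST_PROB_THRESHOLD,
        nms_thresh: float = STARDIST_NMS_THRESHOLD,
    ) -> None:
        try:
            from stardist.models import StarDist2D  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise SegmenterUnavailableError(
                "stardist is not installed; use builtin_blob_segmenter or "
                "file-supplied masks instead"
            ) from exc
        self._model = StarDist2D.from_pretrained(model_name)
        self.prob_thresh = prob_thresh
        self.nms_thresh = nms_thresh

    def __call__(self, img: np.ndarray) -> np.ndarray:  # pragma: no cover
        labels, _ = self._model.predict_instances(
            img, prob_thresh=self.prob_thresh, nms_thresh=self.nms_thresh
        )
        return labels


def segment_nuclei(
    img: NormalizedImage | np.ndarray,
    backend: Callable[[np.ndarray], np.ndarray] = builtin_blob_segmenter,
) -> LabelMask:
    """Run a segmenter backend and return a compacted :class:`LabelMask`.

    The backend receives the normalized luminance raster (Y channel) and
    must return an integer label raster of identical height/width.
    """
    raster = img.luminance if isinstance(img, NormalizedImage) else np.asarray(img)
    labels = np.asarray(backend(raster))
    if labels.shape != raster.shape[:2]:
        raise ValueError(
            f"backend returned shape {labels.shape}, expected {raster.shape[:2]}"
        )
    return LabelMask.from_labels(labels)


def regions_from_mask(
    img_gray: np.ndarray,
    mask: LabelMask | np.ndarray,
    min_area: int = 15,
    border_policy: Literal["keep", "drop"] = "keep",
) -> list[RegionPatch]:
    """Crop one :class:`RegionPatch` per surviving labeled region.

    Regions smaller than ``min_area`` pixels are removed;
    ``border_policy="drop"`` additionally removes regions touching the
    image boundary. Patches are cropped to the tight bounding box.
    """
    gray = np.asarray(img_gray, dtype=np.float64)
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if gray.shape != labels.shape:
        raise ValueError("image and mask shapes must agree")
    h, w = labels.shape
    patches: list[RegionPatch] = []
    objects = ndimage.find_objects(labels)
    for rid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == rid
        area = int(region.sum())
        if area < min_area:
            continue
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        if border_policy == "drop" and (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
            continue
        patches.append(
            RegionPatch(
                gray=gray[sl].copy(),
                mask=region,
                region_id=rid,
                area=area,
                bbox=(r0, c0, r1, c1),
            )
        )
    return patches


def read_mask(path: str | Path) -> LabelMask:
    """Read a 16-bit single-channel PNG/TIFF label image."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        labels = tifffile.imread(path)
    else:
        from PIL import Image

        with Image.open(path) as im:
            labels = np.asarray(im)
    return LabelMask.from_labels(labels.astype(np.int32))


def write_mask(mask: LabelMask | np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit single-channel PNG or TIFF."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many regions for a 16-bit mask")
    path = Path(path)
    data = labels.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data)
    else:
        from PIL import Image

        Image.fromarray(data).save(path)
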