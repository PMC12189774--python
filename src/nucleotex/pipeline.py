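"""End-to-end feature extraction: dataset records → feature tables.

Glue between the stages: color conversion and normalization, nuclei
masks (ground truth, file-supplied, or the builtin segmenter),
per-nucleus texture descriptors aggregated to tile level, and tile
embeddings. Produces the two aligned tables (handcrafted, embedded)
that the classifier stack consumes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .embeddings import SurrogateEmbedder
from .image_prep import Tile, percentile_normalize, rgb_to_xyz
from .segmentation import (LabelMask, builtin_blob_segmenter, regions_from_mask,
                           segment_nuclei)
from .texture import TextureConfig, aggregate_features, nucleus_feature_vector


def normalize_record(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RGB uint8 → (normalized XYZ raster, luminance raster)."""
    xyz = rgb_to_xyz(pixels)
    norm = percentile_normalize(xyz)
    return norm.pixels, norm.luminance


def handcrafted_table(records: Iterable[Mapping], cfg: TextureConfig | None = None,
                      use_masks: bool = True, min_area: int = 15,
                      border_policy: str = "keep") -> pd.DataFrame:
    """Aggregated per-tile handcrafted features, one row per record.

    Records need ``sample_id``, ``label``, ``pixels``; when ``use_masks``
    and a record carries a ``mask`` it is used, otherwise the builtin
    segmenter runs on the normalized luminance.
    """
    cfg = cfg or TextureConfig()
    rows = []
    for rec in records:
        _, lum = normalize_record(rec["pixels"])
        mask = rec.get("mask") if use_masks else None
        if mask is None:
            mask = segment_nuclei(lum, backend=builtin_blob_segmenter)
        elif not isinstance(mask, LabelMask):
            mask = LabelMask.from_labels(np.asarray(mask))
        patches = regions_from_mask(lum, mask, min_area=min_area,
                                    border_policy=border_policy)
        nuc = [nucleus_feature_vector(p, cfg) for p in patches]
        agg = aggregate_features(nuc, level_target="tile")
        row = {"sample_id": rec["sample_id"], "label": rec["label"]}
        row.update(agg.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def embedding_table(records: Iterable[Mapping],
                    embedder: Callable | None = None) -> pd.DataFrame:
    """Per-tile embeddings, one row per record (sample_id, label, e0..)."""
    embedder = embedder or SurrogateEmbedder()
    rows = []
    for rec in records:
        norm, _ = normalize_record(rec["pixels"])
        tile = Tile(pixels=norm, origin=(0, 0), parent_id=rec["sample_id"])
        side = getattr(embedder, "expected_side", None)
        if side is not None and tile.side != side:
            from .image_prep import resize_tile

            tile = resize_tile(tile, side)
        vec = np.asarray(embedder(tile), dtype=np.float64)
        row = {"sample_id": rec["sample_id"], "label": rec["label"]}
        row.update({f"e{i}": v for i, v in enumerate(vec)})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrices(handcrafted: pd.DataFrame, embedded: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Align the two tables by sample_id → (X_h, X_e, y, sample_ids)."""
    h = handcrafted.sort_values("sample_id").reset_index(drop=True)
    e = embedded.sort_values("sample_id").reset_index(drop=True)
    if list(h["sample_id"]) != list(e["sample_id"]):
        raise ValueError("handcrafted and embedded tables have different samples")
    if list(h["label"]) != list(e["label"]):
        raise ValueError("label mismatch between feature tables")
    Xh = h.drop(columns=["sample_id", "label"]).to_numpy(dtype=np.float64)
    Xe = e.drop(columns=["sample_id", "label"]).to_numpy(dtype=np.float64)
    return Xh, Xe, h["label"].to_numpy(), list(h["sample_id"])


def load_records_from_directory(root: str | Path,
                                with_masks: bool = True) -> list[dict]:
    """Read a directory-per-class dataset (optionally with ``*_mask`` files)."""
    from .image_prep import iter_dataset
    from .segmentation import read_mask

    root = Path(root)
    records = []
    for img in iter_dataset(root):
        rec = {"sample_id": img.source_id, "label": img.class_label,
               "pixels": img.pixels, "mask": None}
        if with_masks:
            for ext in (".png", ".tif", ".tiff"):
                cand = root / img.class_label / f"{img.source_id}_mask{ext}"
                if cand.exists():
                    rec["mask"] = read_mask(cand)
                    break
        records.append(rec)
    return records
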