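"""Tile embeddings through a pluggable embedder contract.

Two backends satisfy the contract (tile in, fixed-length finite vector out):

* ``HOptimusEmbedder`` — adapter for the H-optimus-0 pathology foundation
  model (ViT-g/14, 1536-dim embeddings, 224×224 input). The transformer is
  an external pretrained artifact; this class only forwards tiles when the
  optional dependency stack is installed.
* ``SurrogateEmbedder`` — a deterministic offline stand-in: a fixed bank of
  tile summary statistics (channel means/variances, gradient-magnitude
  histogram, block-mean grid) projected through a seed-derived
  pseudorandom matrix. It is not a neural network and makes no claim to
  histological semantics; it exists so the full pipeline is testable
  without GPU weights.

Precomputed embedding tables (CSV keyed by sample_id) are first-class, so
users with GPU-computed embeddings never run a model through this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .image_prep import Tile

#: embedding width of the pathology foundation model
FOUNDATION_DIM = 1536
#: default surrogate width used in tests (fast)
SURROGATE_DIM = 64


class EmbedderUnavailableError(RuntimeError):
    """Raised when an optional embedding backend cannot be imported."""


@dataclass
class TileEmbedding:
    """Fixed-length embedding vector with provenance."""

    vector: np.ndarray
    tile_ref: tuple[str, tuple[int, int]]
    embedder_id: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding entries must be finite")


def _tile_stats(pixels: np.ndarray) -> np.ndarray:
    """Fixed summary-statistic bank: 6 channel moments, 8 gradient-histogram
    bins, 16 block means (4×4 grid of the luminance channel)."""
    px = np.asarray(pixels, dtype=np.float64)
    if px.ndim == 2:
        px = px[..., None]
    chans = px.shape[2]
    means = px.reshape(-1, chans).mean(axis=0)
    var = px.reshape(-1, chans).var(axis=0)
    if chans == 1:
        means = np.repeat(means, 3)
        var = np.repeat(var, 3)
    else:
        means, var = means[:3], var[:3]
    lum = px.mean(axis=2)
    gy, gx = np.gradient(lum)
    gmag = np.hypot(gx, gy)
    hist, _ = np.histogram(gmag, bins=8, range=(0, max(gmag.max(), 1e-12)))
    hist = hist / max(gmag.size, 1)
    h, w = lum.shape
    rb = np.array_split(np.arange(h), 4)
    cb = np.array_split(np.arange(w), 4)
    blocks = np.array([lum[np.ix_(r, c)].mean() for r in rb for c in cb])
    return np.concatenate([means, var, hist, blocks])


class SurrogateEmbedder:
    """Deterministic tile embedder: statistic bank × pseudorandom projection.

    Identical (tile, dim, seed) always produce identical vectors; changing
    the seed changes the projection matrix and hence the embedding.
    """

    def __init__(self, dim: int = SURROGATE_DIM, seed: int = 0) -> None:
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        n_stats = 30  # 3 means + 3 vars + 8 gradient bins + 16 block means
        self._proj = rng.standard_normal((dim, n_stats)) / np.sqrt(n_stats)
        self.embedder_id = f"surrogate-d{dim}-s{seed}"

    def __call__(self, tile: Tile | np.ndarray) -> np.ndarray:
        px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
        return self._proj @ _tile_stats(px)


class HOptimusEmbedder:  # pragma: no cover - optional external weights
    """Adapter for the H-optimus-0 foundation model (1536-dim, 224 input)."""

    expected_side = 224
    embedder_id = "h-optimus-0"

    def __init__(self) -> None:
        try:
            import timm  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:
            raise EmbedderUnavailableError(
                "H-optimus-0 requires torch+timm with downloaded weights; "
                "use SurrogateEmbedder or a precomputed embedding table"
            ) from exc
        self._torch = torch
        self._model = timm.create_model(
            "hf-hub:bioptimus/H-optimus-0", pretrained=True,
            init_values=1e-5, dynamic_img_size=False,
        ).eval()

    def __call__(self, tile: Tile | np.ndarray) -> np.ndarray:
        px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
        t = self._torch.from_numpy(
            np.ascontiguousarray(px.transpose(2, 0, 1))[None].astype("float32")
        )
        with self._torch.no_grad():
            return self._model(t).numpy().ravel().astype(np.float64)


def embed_tile(t: Tile, backend: Callable[[Tile], np.ndarray],
               embedder_id: str | None = None) -> TileEmbedding:
    """Run a backend on one tile, tagging the result with its provenance."""
    vec = np.asarray(backend(t), dtype=np.float64)
    eid = embedder_id or getattr(backend, "embedder_id", backend.__class__.__name__)
    return TileEmbedding(vector=vec, tile_ref=(t.parent_id, t.origin),
                         embedder_id=eid)


def embed_tiles(tiles: Sequence[Tile],
                backend: Callable[[Tile], np.ndarray]) -> list[TileEmbedding]:
    """Embed tiles in order, enforcing a constant dimension across the set."""
    out: list[TileEmbedding] = []
    dim: int | None = None
    for t in tiles:
        emb = embed_tile(t, backend)
        if dim is None:
            dim = emb.vector.size
        elif emb.vector.size != dim:
            raise ValueError(
                f"embedding dimension mismatch: {emb.vector.size} != {dim}"
            )
        out.append(emb)
    return out


def write_embedding_table(embeddings: Sequence[TileEmbedding],
                          sample_ids: Sequence[str],
                          path: str | Path) -> None:
    """Write CSV with columns sample_id, e0..e{D-1}."""
    mat = np.stack([e.vector for e in embeddings])
    df = pd.DataFrame(mat, columns=[f"e{i}" for i in range(mat.shape[1])])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def read_embedding_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed embedding CSV (sample_id, e0..e{D-1}).

    All embedding columns must be numeric and finite; a table mixing
    dimensions cannot arise from a rectangular CSV, but NaNs (ragged
    sources) are rejected.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("embedding table must have a sample_id column")
    emb_cols = [c for c in df.columns if c != "sample_id"]
    if df[emb_cols].isna().any().any():
        raise ValueError("embedding table contains missing values")
    return df
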