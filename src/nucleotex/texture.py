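"""Mask-aware handcrafted texture descriptors per nucleus.

Implements the four descriptor families computed inside each segmented
nucleus on the quantized luminance patch:

* FOS   — first-order statistics of the intensity distribution;
* GLCM  — gray-level co-occurrence matrices over distances D = {1,2,3} and
          angles Θ = {0°,45°,90°,135°} (directional, unsymmetrized);
* GLRLM — gray-level run-length matrices over the same four angles;
* GLSZM — gray-level size-zone matrices under 4- and 8-connectivity.

All matrix builders are mask-aware: pixel pairs, runs, and zones never
cross the nucleus boundary. Quantized patches use the integer sentinel
``BACKGROUND`` (-1) outside the mask.

Offset convention: image rows increase downward, so angle θ uses the
pixel offset (Δrow, Δcol) = (−d·sinθ, d·cosθ); e.g. 45° is (−d, +d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .segmentation import RegionPatch

logger = logging.getLogger(__name__)

#: sentinel for pixels outside the nucleus mask in quantized patches
BACKGROUND = -1

#: (Δrow, Δcol) unit offsets per angle in degrees
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

FOS_NAMES = ("mean", "variance", "skewness", "kurtosis",
             "min", "max", "median", "entropy")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")
GLRLM_NAMES = ("sre", "lre", "run_percentage",
               "gray_level_nonuniformity", "run_length_nonuniformity")
GLSZM_NAMES = ("sze", "lze", "zone_percentage", "gray_level_nonuniformity")
SHAPE_NAMES = ("area", "aspect_ratio")


@dataclass
class TextureConfig:
    """Quantization and directionality settings for all texture matrices.

    Defaults: G = 32 gray levels (per-patch min–max binning),
    D = {1,2,3}, Θ = {0°,45°,90°,135°}, C = {4,8}, no symmetrization.
    """

    n_levels: int = 32
    distances: tuple[int, ...] = (1, 2, 3)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    connectivities: tuple[int, ...] = (4, 8)
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"unsupported angle {a}; choose from 0/45/90/135")
        for c in self.connectivities:
            if c not in (4, 8):
                raise ValueError("connectivity must be 4 or 8")

    def to_json(self) -> str:
        import json

        return json.dumps({"n_levels": self.n_levels,
                           "distances": list(self.distances),
                           "angles": list(self.angles),
                           "connectivities": list(self.connectivities),
                           "symmetric": self.symmetric})

    @classmethod
    def from_json(cls, payload: str) -> "TextureConfig":
        import json

        d = json.loads(payload)
        return cls(n_levels=d["n_levels"], distances=tuple(d["distances"]),
                   angles=tuple(d["angles"]),
                   connectivities=tuple(d["connectivities"]),
                   symmetric=d.get("symmetric", False))


@dataclass
class FeatureVector:
    """Ordered named numeric vector at nucleus, tile, or image level."""

    values: np.ndarray
    names: list[str]
    level: str = "nucleus"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values and names lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CooccurrenceMatrix:
    """G×G pair-count matrix at one (distance, angle)."""

    counts: np.ndarray
    d: int
    theta: int
    normalized: bool = False

    @property
    def degenerate(self) -> bool:
        return self.counts.sum() == 0

    def normalize(self) -> "CooccurrenceMatrix":
        total = self.counts.sum()
        if total == 0:
            return CooccurrenceMatrix(self.counts.astype(np.float64),
                                      self.d, self.theta, normalized=True)
        return CooccurrenceMatrix(self.counts / total, self.d, self.theta,
                                  normalized=True)

    def marginals(self) -> tuple[float, float, float, float]:
        """(μi, μj, σi, σj) recomputed from the normalized matrix."""
        p = self.counts / self.counts.sum() if not self.normalized else self.counts
        g = p.shape[0]
        idx = np.arange(g)
        pi, pj = p.sum(axis=1), p.sum(axis=0)
        mu_i, mu_j = float(idx @ pi), float(idx @ pj)
        sig_i = float(np.sqrt(((idx - mu_i) ** 2) @ pi))
        sig_j = float(np.sqrt(((idx - mu_j) ** 2) @ pj))
        return mu_i, mu_j, sig_i, sig_j


@dataclass
class RunLengthMatrix:
    """counts[g, r-1] = number of maximal runs of level g with length r."""

    counts: np.ndarray
    theta: int

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())


@dataclass
class SizeZoneMatrix:
    """counts[g, s-1] = number of connected zones of level g with size s."""

    counts: np.ndarray
    connectivity: int

    @property
    def n_zones(self) -> float:
        return float(self.counts.sum())


def _as_levels(patch, n_levels: int | None = None) -> tuple[np.ndarray, int]:
    """Accept a quantized int array (BACKGROUND sentinel) and infer G."""
    lv = np.asarray(patch)
    if not np.issubdtype(lv.dtype, np.integer):
        raise TypeError("expected an integer quantized patch; call quantize() first")
    if n_levels is None:
        n_levels = int(lv.max()) + 1 if lv.size and lv.max() >= 0 else 1
    return lv, max(n_levels, 1)


def quantize(patch: RegionPatch | np.ndarray, n_levels: int = 32,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Bin masked pixel values into integer levels 0..G−1.

    Per-patch min–max binning: level = floor((v − min)/(max − min)·G),
    clipped to G−1. Constant patches map to level 0. Pixels outside the
    mask carry the ``BACKGROUND`` sentinel.
    """
    if isinstance(patch, RegionPatch):
        gray, m = patch.gray, patch.mask
    else:
        gray = np.asarray(patch, dtype=np.float64)
        m = np.ones(gray.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("quantize requires at least one mask pixel")
    vals = gray[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(gray.shape, BACKGROUND, dtype=np.int32)
    if hi <= lo:
        out[m] = 0
        return out
    levels = np.floor((gray[m] - lo) / (hi - lo) * n_levels).astype(np.int32)
    out[m] = np.clip(levels, 0, n_levels - 1)
    return out


def fos_features(values: np.ndarray | RegionPatch,
                 quantized: np.ndarray | None = None,
                 n_levels: int = 32) -> FeatureVector:
    """First-order statistics of the masked intensity distribution.

    Moments use the population (n) denominator; kurtosis is non-excess
    (a normal distribution scores 3). Entropy is base-2 over the G-level
    quantized histogram (0·log0 := 0); when no quantized patch is given
    the raw values are quantized first. Single-pixel / constant patches:
    variance 0, skewness and kurtosis 0 by convention.
    """
    if isinstance(values, RegionPatch):
        if quantized is None:
            quantized = quantize(values, n_levels)
        values = values.masked_values
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("fos_features requires at least one pixel")
    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    if m2 > 0:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew, kurt = m3 / m2**1.5, m4 / m2**2
    else:
        skew = kurt = 0.0
        if v.size == 1:
            logger.debug("single-pixel patch: skewness/kurtosis set to 0")
    if quantized is None:
        q = quantize(v, n_levels)
    else:
        q = quantized
    levels = q[q != BACKGROUND]
    hist = np.bincount(levels, minlength=1).astype(np.float64)
    p = hist[hist > 0] / levels.size
    entropy = float(-(p * np.log2(p)).sum())
    vals = [mean, m2, skew, kurt, float(v.min()), float(v.max()),
            float(np.median(v)), entropy]
    return FeatureVector(values=np.array(vals),
                         names=[f"fos_{n}" for n in FOS_NAMES])


def glcm(patch, d: int, theta: int, n_levels: int | None = None,
         symmetric: bool = False) -> CooccurrenceMatrix:
    """Gray-level co-occurrence counts at distance ``d`` and angle ``theta``.

    Counts ordered pairs (p, p + offset) where both pixels lie inside the
    mask; accumulation is directional (asymmetric) unless ``symmetric``.
    A (d, θ) with no valid pair yields a zero matrix flagged degenerate.
    """
    lv, g = _as_levels(patch, n_levels)
    if d < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = ANGLE_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = lv.shape
    counts = np.zeros((g, g), dtype=np.int64)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 < r1 and c0 < c1:
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a != BACKGROUND) & (b != BACKGROUND)
        if valid.any():
            pairs = a[valid].astype(np.int64) * g + b[valid]
            counts += np.bincount(pairs, minlength=g * g).reshape(g, g)
    if symmetric:
        counts = counts + counts.T
    m = CooccurrenceMatrix(counts=counts, d=d, theta=theta)
    if m.degenerate:
        logger.debug("degenerate GLCM at d=%d theta=%d", d, theta)
    return m


def glcm_features(m: CooccurrenceMatrix) -> FeatureVector:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    Correlation is defined as 0 when either marginal deviation vanishes
    (constant patch); a degenerate zero matrix yields all-zero features.
    """
    p = m.normalize().counts if not m.normalized else m.counts
    if p.sum() == 0:
        return FeatureVector(values=np.zeros(4),
                             names=list(GLCM_NAMES), flags=["degenerate"])
    g = p.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i, mu_j, sig_i, sig_j = CooccurrenceMatrix(p, m.d, m.theta, True).marginals()
    denom = sig_i * sig_j
    if denom > 0:
        correlation = float((((i - mu_i) * (j - mu_j)) * p).sum() / denom)
    else:
        correlation = 0.0
    return FeatureVector(values=np.array([contrast, correlation, energy,
                                          homogeneity]),
                         names=list(GLCM_NAMES))


def _runs_of_line(line: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (level, length) for maximal equal-level runs, skipping sentinel."""
    n = line.size
    i = 0
    while i < n:
        v = line[i]
        j = i + 1
        while j < n and line[j] == v:
            j += 1
        if v != BACKGROUND:
            yield int(v), j - i
        i = j


def _direction_lines(lv: np.ndarray, theta: int) -> list[np.ndarray]:
    """Scan lines of the patch along direction θ."""
    h, w = lv.shape
    if theta == 0:
        return [lv[r, :] for r in range(h)]
    if theta == 90:
        return [lv[:, c] for c in range(w)]
    # 45°: runs along (−1,+1); these are the diagonals of the vertically
    # flipped patch. 135°: along (−1,−1) — diagonals of the patch itself.
    base = np.flipud(lv) if theta == 45 else lv
    return [np.diagonal(base, offset=k).copy()
            for k in range(-(h - 1), w)]


def glrlm(patch, theta: int, n_levels: int | None = None) -> RunLengthMatrix:
    """Run-length counts: maximal same-level runs along direction θ.

    Runs are broken by the mask boundary; counts[g, r−1] is the number of
    maximal runs of level g and length r.
    """
    lv, g = _as_levels(patch, n_levels)
    if not (lv != BACKGROUND).any():
        raise ValueError("glrlm requires a non-empty mask")
    rmax = max(lv.shape)
    counts = np.zeros((g, rmax), dtype=np.int64)
    for line in _direction_lines(lv, theta):
        for level, length in _runs_of_line(np.asarray(line)):
            counts[level, length - 1] += 1
    return RunLengthMatrix(counts=counts, theta=theta)


def glrlm_features(r: RunLengthMatrix) -> FeatureVector:
    """SRE, LRE, run percentage, and the two nonuniformity measures.

    SRE = Σ N(g,r)/r² / N_runs and LRE = Σ r²·N(g,r) / N_runs; run
    percentage divides runs by traversed mask pixels; gray-level and
    run-length nonuniformity follow the standard Galloway definitions.
    """
    n_runs = r.counts.sum()
    if n_runs == 0:
        raise ValueError("run-length matrix has zero runs")
    lens = np.arange(1, r.counts.shape[1] + 1, dtype=np.float64)
    per_len = r.counts.sum(axis=0).astype(np.float64)
    per_lvl = r.counts.sum(axis=1).astype(np.float64)
    n_pixels = float((per_len * lens).sum())
    sre = float((per_len / lens**2).sum() / n_runs)
    lre = float((per_len * lens**2).sum() / n_runs)
    rp = float(n_runs / n_pixels)
    gln = float((per_lvl**2).sum() / n_runs)
    rln = float((per_len**2).sum() / n_runs)
    return FeatureVector(values=np.array([sre, lre, rp, gln, rln]),
                         names=list(GLRLM_NAMES))


def glszm(patch, connectivity: int = 4,
          n_levels: int | None = None) -> SizeZoneMatrix:
    """Size-zone counts: connected equal-level zones under 4/8 adjacency."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lv, g = _as_levels(patch, n_levels)
    inside = lv != BACKGROUND
    if not inside.any():
        raise ValueError("glszm requires a non-empty mask")
    smax = int(inside.sum())
    counts = np.zeros((g, smax), dtype=np.int64)
    struct = _STRUCTS[connectivity]
    for level in np.unique(lv[inside]):
        labeled, n = ndimage.label(lv == level, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            counts[level, s - 1] += 1
    return SizeZoneMatrix(counts=counts, connectivity=connectivity)


def glszm_features(z: SizeZoneMatrix) -> FeatureVector:
    """SZE, LZE, zone percentage, gray-level nonuniformity over zones."""
    n_zones = z.counts.sum()
    if n_zones == 0:
        raise ValueError("size-zone matrix has zero zones")
    sizes = np.arange(1, z.counts.shape[1] + 1, dtype=np.float64)
    per_size = z.counts.sum(axis=0).astype(np.float64)
    per_lvl = z.counts.sum(axis=1).astype(np.float64)
    n_pixels = float((per_size * sizes).sum())
    sze = float((per_size / sizes**2).sum() / n_zones)
    lze = float((per_size * sizes**2).sum() / n_zones)
    zp = float(n_zones / n_pixels)
    gln = float((per_lvl**2).sum() / n_zones)
    return FeatureVector(values=np.array([sze, lze, zp, gln]),
                         names=list(GLSZM_NAMES))


def nucleus_feature_vector(patch: RegionPatch,
                           cfg: TextureConfig | None = None) -> FeatureVector:
    """Full handcrafted descriptor for one nucleus (86 named values).

    Fixed order: 8 FOS, then 4 GLCM features per (d, θ) in D×Θ (48), then
    5 GLRLM features per θ (20), then 4 GLSZM features per connectivity
    (8), then area and bounding-box aspect ratio (2). Degenerate
    sub-operations contribute flagged zeros, never NaN.
    """
    cfg = cfg or TextureConfig()
    q = quantize(patch, cfg.n_levels)
    names: list[str] = []
    values: list[float] = []
    flags: list[str] = []

    fos = fos_features(patch.masked_values, quantized=q, n_levels=cfg.n_levels)
    names += fos.names
    values += fos.values.tolist()

    for d in cfg.distances:
        for theta in cfg.angles:
            m = glcm(q, d, theta, n_levels=cfg.n_levels, symmetric=cfg.symmetric)
            fv = glcm_features(m)
            prefix = f"glcm_d{d}_a{theta}_"
            names += [prefix + n for n in GLCM_NAMES]
            values += fv.values.tolist()
            if fv.flags:
                flags.append(prefix.rstrip("_"))

    for theta in cfg.angles:
        fv = glrlm_features(glrlm(q, theta, n_levels=cfg.n_levels))
        names += [f"glrlm_a{theta}_{n}" for n in GLRLM_NAMES]
        values += fv.values.tolist()

    for conn in cfg.connectivities:
        fv = glszm_features(glszm(q, conn, n_levels=cfg.n_levels))
        names += [f"glszm_c{conn}_{n}" for n in GLSZM_NAMES]
        values += fv.values.tolist()

    r0, c0, r1, c1 = patch.bbox
    height, width = max(r1 - r0, 1), max(c1 - c0, 1)
    names += [f"shape_{n}" for n in SHAPE_NAMES]
    values += [float(patch.area), height / width]

    return FeatureVector(values=np.array(values), names=names,
                         level="nucleus", flags=flags)


def aggregate_features(per_nucleus: Sequence[FeatureVector],
                       level_target: str = "tile") -> FeatureVector:
    """Pool nucleus vectors to one sample vector: per-feature mean and
    population std across nuclei, plus the nucleus count (2·86 + 1 values).

    Aggregation is permutation-invariant. An empty input yields the
    designated all-zero "no-nuclei" vector (count 0, flagged); names are
    taken from a reference config so downstream column alignment holds.
    """
    if len(per_nucleus) == 0:
        ref = _reference_names()
        names = ([n + "_mean" for n in ref] + [n + "_std" for n in ref]
                 + ["nucleus_count"])
        return FeatureVector(values=np.zeros(len(names)), names=names,
                             level=level_target, flags=["no-nuclei"])
    names0 = per_nucleus[0].names
    for fv in per_nucleus[1:]:
        if fv.names != names0:
            raise ValueError("heterogeneous feature names across nuclei")
    mat = np.stack([fv.values for fv in per_nucleus])
    means, stds = mat.mean(axis=0), mat.std(axis=0)
    names = ([n + "_mean" for n in names0] + [n + "_std" for n in names0]
             + ["nucleus_count"])
    values = np.concatenate([means, stds, [float(len(per_nucleus))]])
    return FeatureVector(values=values, names=names, level=level_target)


def _reference_names(cfg: TextureConfig | None = None) -> list[str]:
    cfg = cfg or TextureConfig()
    names = [f"fos_{n}" for n in FOS_NAMES]
    for d in cfg.distances:
        for theta in cfg.angles:
            names += [f"glcm_d{d}_a{theta}_{n}" for n in GLCM_NAMES]
    for theta in cfg.angles:
        names += [f"glrlm_a{theta}_{n}" for n in GLRLM_NAMES]
    for conn in cfg.connectivities:
        names += [f"glszm_c{conn}_{n}" for n in GLSZM_NAMES]
    names += [f"shape_{n}" for n in SHAPE_NAMES]
    return names
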