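"""Similarity-preserving gene -> pixel mapping and per-sample image rasterization.

The transform follows the DeepInsight recipe: each gene's expression profile
across samples is embedded into the plane (t-SNE or kernel PCA), the
minimum-area rotated rectangle around the embedded cloud is found via the
convex hull, the cloud is rotated so that rectangle is axis-aligned, and the
coordinates are rescaled onto an integer pixel grid. Each sample's image then
holds, at every occupied pixel, the mean normalized expression of the genes
assigned to it. The fitted map is invertible: every pixel knows its genes,
which is what lets pixel attributions be mapped back to genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point
from sklearn.decomposition import KernelPCA
from sklearn.manifold import TSNE

from .io import ExpressionMatrix

__all__ = [
    "FeatureMap",
    "ImageStack",
    "normalize_norm2",
    "apply_normalization",
    "embed_features",
    "min_area_rectangle",
    "fit_feature_map",
    "transform_to_images",
    "pixels_to_genes",
]

FORMAT_VERSION = 1


def normalize_norm2(m: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Per-gene log + min-max normalization to [0, 1] ("norm-2").

    Each gene's values are transformed by log2(x + 1) and then min-max scaled
    using that gene's own (min, max) on the log scale. Genes that are constant
    across samples map to 0. Returns the normalized matrix together with the
    per-gene (min, max) parameters needed to normalize held-out samples with
    the training-fold statistics.
    """
    logged = np.log2(m.values + 1.0)
    lo = logged.min(axis=1)
    hi = logged.max(axis=1)
    params = pd.DataFrame({"min": lo, "max": hi}, index=pd.Index(m.gene_ids, name="gene_id"))
    return _apply(m, logged, params), params


def apply_normalization(m: ExpressionMatrix, params: pd.DataFrame) -> ExpressionMatrix:
    """Normalize with previously fitted per-gene (min, max); clip to [0, 1].

    Values outside a gene's training range (possible on held-out folds) are
    clipped so pixel values stay in range.
    """
    missing = [g for g in m.gene_ids if g not in params.index]
    if missing:
        raise KeyError(f"genes without normalization parameters: {missing[:5]}")
    logged = np.log2(m.values + 1.0)
    return _apply(m, logged, params.loc[m.gene_ids])


def _apply(m: ExpressionMatrix, logged: np.ndarray, params: pd.DataFrame) -> ExpressionMatrix:
    lo = params["min"].to_numpy()[:, None]
    hi = params["max"].to_numpy()[:, None]
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (logged - lo) / span
    scaled[np.broadcast_to(span == 0, scaled.shape)] = 0.0
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), np.clip(scaled, 0.0, 1.0))


def embed_features(
    m: ExpressionMatrix,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    kpca_kernel: str = "linear",
) -> np.ndarray:
    """Embed each gene's cross-sample profile into 2D.

    The matrix is used gene-major (genes are the points, samples the
    dimensions), so genes with similar profiles land near each other.
    Deterministic for a given seed.
    """
    if m.n_genes < 3:
        raise ValueError("need at least 3 genes to embed (bounding rectangle undefined)")
    X = m.values  # genes x samples
    if method == "tsne":
        perp = min(perplexity, (m.n_genes - 1) / 3.0)
        ts = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
        return np.asarray(ts.fit_transform(X), dtype=np.float64)
    if method == "kpca":
        kp = KernelPCA(n_components=2, kernel=kpca_kernel, random_state=seed)
        return np.asarray(kp.fit_transform(X), dtype=np.float64)
    raise ValueError(f"unknown embedding method {method!r}")


def min_area_rectangle(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-area rotated rectangle of a 2D point set.

    Returns ``(angle, corners)`` where ``corners`` is a (4, 2) array and
    ``angle`` (radians, in [0, pi/2)) is the tilt of one rectangle side, i.e.
    rotating the points by ``-angle`` makes the rectangle axis-aligned. By the
    rotating-calipers theorem the optimum has a side collinear with a convex
    hull edge. Degenerate inputs (single point, collinear points) yield a
    zero-extent rectangle; the grid rescaling pads zero extents downstream.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("points must be a non-empty (n, 2) array")
    geom = MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle
    if isinstance(geom, Point):
        c = np.repeat(pts[:1], 4, axis=0)
        return 0.0, c
    if isinstance(geom, LineString):
        (x0, y0), (x1, y1) = geom.coords
        angle = np.arctan2(y1 - y0, x1 - x0) % np.pi
        corners = np.array([[x0, y0], [x1, y1], [x1, y1], [x0, y0]])
    else:
        corners = np.asarray(geom.exterior.coords)[:4]
        e = corners[1] - corners[0]
        angle = np.arctan2(e[1], e[0]) % np.pi
    if angle >= np.pi / 2:  # canonicalize using the perpendicular side
        angle -= np.pi / 2
    return float(angle), corners


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, s], [-s, c]]).T


@dataclass
class FeatureMap:
    """Fitted gene -> pixel assignment with its inverse.

    ``pixel_of_gene`` maps every gene to exactly one (row, col);
    ``genes_of_pixel`` is its exact inverse (pixel -> tuple of genes).
    """

    grid_size: int
    method: str
    seed: int
    rotation_angle: float
    gene_ids: list[str]
    embedding_coords: np.ndarray  # (n_genes, 2), pre-rotation
    rows: np.ndarray  # (n_genes,) int
    cols: np.ndarray
    normalization_params: pd.DataFrame | None = None
    norm_variant: str = "log2-minmax"
    genes_of_pixel: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if np.any((self.rows < 0) | (self.rows >= self.grid_size)) or np.any(
            (self.cols < 0) | (self.cols >= self.grid_size)
        ):
            raise ValueError("pixel coordinates out of grid")
        inv: dict[tuple[int, int], list[str]] = {}
        for g, r, c in zip(self.gene_ids, self.rows, self.cols):
            inv.setdefault((int(r), int(c)), []).append(g)
        self.genes_of_pixel = {k: tuple(v) for k, v in inv.items()}
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def pixel_of_gene(self, gene_id: str) -> tuple[int, int]:
        i = self._index[gene_id]
        return int(self.rows[i]), int(self.cols[i])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def save(self, path) -> None:
        """Serialize to a single versioned JSON archive (header + two tables)."""
        norm = None
        if self.normalization_params is not None:
            p = self.normalization_params
            norm = [[g, float(p.at[g, "min"]), float(p.at[g, "max"])] for g in p.index]
        doc = {
            "format_version": FORMAT_VERSION,
            "header": {
                "grid_size": self.grid_size,
                "method": self.method,
                "seed": self.seed,
                "rotation_angle": self.rotation_angle,
                "norm_variant": self.norm_variant,
            },
            "pixels": [
                [g, int(r), int(c)] for g, r, c in zip(self.gene_ids, self.rows, self.cols)
            ],
            "embedding": self.embedding_coords.tolist(),
            "normalization": norm,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "FeatureMap":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported feature-map format {doc.get('format_version')}")
        h = doc["header"]
        genes = [p[0] for p in doc["pixels"]]
        norm = None
        if doc.get("normalization") is not None:
            norm = pd.DataFrame(
                [(r[1], r[2]) for r in doc["normalization"]],
                index=pd.Index([r[0] for r in doc["normalization"]], name="gene_id"),
                columns=["min", "max"],
            )
        return cls(
            grid_size=h["grid_size"],
            method=h["method"],
            seed=h["seed"],
            rotation_angle=h["rotation_angle"],
            gene_ids=genes,
            embedding_coords=np.asarray(doc["embedding"], dtype=np.float64),
            rows=np.array([p[1] for p in doc["pixels"]]),
            cols=np.array([p[2] for p in doc["pixels"]]),
            normalization_params=norm,
            norm_variant=h.get("norm_variant", "log2-minmax"),
        )


@dataclass
class ImageStack:
    """Per-sample single-channel images with values in [0, 1]."""

    sample_ids: list[str]
    images: np.ndarray  # (n_samples, grid, grid) float32

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[0] != len(self.sample_ids):
            raise ValueError("images must be (n_samples, grid, grid)")
        if self.images.size and (self.images.min() < -1e-6 or self.images.max() > 1 + 1e-6):
            raise ValueError("image values must lie in [0, 1]")
        np.clip(self.images, 0.0, 1.0, out=self.images)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def grid_size(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "ImageStack":
        idx = np.asarray(idx)
        return ImageStack([self.sample_ids[i] for i in idx], self.images[idx])

    def as_nhwc(self) -> np.ndarray:
        return self.images[..., None]


def _coords_to_pixels(coords: np.ndarray, angle: float, grid_size: int):
    rot = _rotate(coords, -angle)
    lo = rot.min(axis=0)
    span = rot.max(axis=0) - lo
    eps = 1e-9
    pix = np.zeros_like(rot)
    for ax in range(2):
        if span[ax] <= 0:
            pix[:, ax] = 0.0  # zero extent padded to a single pixel
        else:
            pix[:, ax] = (rot[:, ax] - lo[ax]) / span[ax] * (grid_size - eps)
    pix = np.floor(pix).astype(int)
    return np.clip(pix, 0, grid_size - 1)


def fit_feature_map(
    m: ExpressionMatrix,
    grid_size: int = 380,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    coords: np.ndarray | None = None,
    normalization_params: pd.DataFrame | None = None,
) -> FeatureMap:
    """Fit the full gene -> pixel transform on a (normalized) matrix.

    Pipeline: embed gene profiles -> minimum-area rectangle -> rotate to
    axis-align -> rescale each axis to [0, grid_size) -> floor to integer
    pixels (half-open bins; points on the maximum boundary land in the last
    pixel). ``coords`` may be passed to reuse a precomputed embedding, in
    which case ``method`` is recorded as "precomputed".
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if coords is None:
        coords = embed_features(m, method=method, seed=seed, perplexity=perplexity)
    else:
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (m.n_genes, 2):
            raise ValueError("coords must be (n_genes, 2)")
        method = "precomputed"
    angle, _ = min_area_rectangle(coords)
    pix = _coords_to_pixels(coords, angle, grid_size)
    return FeatureMap(
        grid_size=grid_size,
        method=method,
        seed=seed,
        rotation_angle=angle,
        gene_ids=list(m.gene_ids),
        embedding_coords=coords,
        rows=pix[:, 1],  # image row = embedded y
        cols=pix[:, 0],
        normalization_params=normalization_params,
    )


def transform_to_images(m: ExpressionMatrix, fm: FeatureMap, agg: str = "mean") -> ImageStack:
    """Rasterize each (normalized) sample onto the fitted pixel grid.

    Pixels holding several genes take the unweighted mean of their normalized
    values ("averaged out"); a median variant is available. Unmapped pixels
    are zero.
    """
    missing = [g for g in m.gene_ids if g not in fm._index]
    if missing:
        raise KeyError(f"genes absent from the feature map: {missing[:5]}")
    gidx = np.array([fm._index[g] for g in m.gene_ids])
    flat = fm.rows[gidx] * fm.grid_size + fm.cols[gidx]
    n_pix = fm.grid_size * fm.grid_size
    vals = m.values  # genes x samples, already in [0, 1]
    if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
        raise ValueError("matrix must be normalized to [0, 1] before rasterization")
    if agg == "mean":
        sums = np.zeros((n_pix, m.n_samples))
        np.add.at(sums, flat, vals)
        counts = np.bincount(flat, minlength=n_pix).astype(float)
        with np.errstate(invalid="ignore"):
            out = sums / counts[:, None]
        out[counts == 0] = 0.0
    elif agg == "median":
        out = np.zeros((n_pix, m.n_samples))
        df = pd.DataFrame(vals)
        for p, grp in df.groupby(flat):
            out[p] = grp.median(axis=0).to_numpy()
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    images = out.T.reshape(m.n_samples, fm.grid_size, fm.grid_size)
    return ImageStack(list(m.sample_ids), images)


def pixels_to_genes(fm: FeatureMap, pixels) -> list[frozenset]:
    """Inverse lookup: gene set for each (row, col); empty set if unmapped."""
    out = []
    for r, c in pixels:
        if not (0 <= r < fm.grid_size and 0 <= c < fm.grid_size):
            raise ValueError(f"pixel ({r}, {c}) outside {fm.grid_size}x{fm.grid_size} grid")
        out.append(frozenset(fm.genes_of_pixel.get((int(r), int(c)), ())))
    return out


def export_images(stack: ImageStack, out_dir) -> Path:
    """Write one 16-bit grayscale PNG per sample plus a manifest TSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, img in zip(stack.sample_ids, stack.images):
        arr = np.round(img.astype(np.float64) * 65535).astype(np.uint16)
        fname = f"{sid}.png"
        Image.fromarray(arr, mode="I;16").save(out_dir / fname)
        rows.append((sid, fname))
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=["sample_id", "file"]).to_csv(manifest, sep="\t", index=False)
    return manifest
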