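"""Dimensionality reduction of the whole parameter space to 2-D.

The projection pipeline always embeds the ENTIRE combinatorial space, not
just a filtered subset, so aggregate overlays stay meaningful.  For vector
metrics the pipeline is encode -> optional chunked incremental PCA (to tame
wide descriptor matrices) -> embedder; for gower/jaccard/precomputed metrics
a pre-computed distance matrix feeds an embedder that accepts one.  The
embedders themselves (UMAP, t-SNE, PCA) are standard library calls behind a
narrow interface — the contribution here is the surrounding pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA, IncrementalPCA

from . import distances as _dist
from .ro_dataset import CampaignDataset, RoDatasetError

__all__ = [
    "ProjectionConfig",
    "Embedding",
    "chunked_pca",
    "project",
    "remove_overlaps",
]

#: Apply the incremental-PCA pre-reduction only above this feature count.
PCA_PREREDUCTION_THRESHOLD = 50


@dataclass(frozen=True)
class ProjectionConfig:
    """Configuration of one projection run.

    ``method_params`` is passed through to the embedder (e.g. ``perplexity``
    for t-SNE, ``n_neighbors``/``min_dist`` for UMAP).
    """

    method: str = "umap"
    metric: str = "gower"
    weights: Mapping[str, float] | None = None
    pca_components: int = 50
    chunk_size: int = 1000
    seed: int = 0
    method_params: Mapping = field(default_factory=dict)
    categorical_mode: str = "labels"

    def __post_init__(self):
        if self.method not in ("umap", "tsne", "pca"):
            raise RoDatasetError(f"unknown projection method {self.method!r}")
        if self.metric not in ("euclidean", "jaccard", "gower", "precomputed"):
            raise RoDatasetError(f"unknown metric {self.metric!r}")
        if self.pca_components < 2:
            raise RoDatasetError("pca_components must be >= 2")
        if self.chunk_size < self.pca_components:
            raise RoDatasetError("chunk_size must be >= pca_components")


@dataclass
class Embedding:
    """2-D coordinates per experiment, with provenance."""

    coords: np.ndarray  # (n, 2)
    config: ProjectionConfig | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise RoDatasetError("embedding coordinates must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise RoDatasetError("embedding coordinates must be finite")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) bounding box."""
        x, y = self.coords[:, 0], self.coords[:, 1]
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())

    def __len__(self) -> int:
        return len(self.coords)


# ---------------------------------------------------------------------------
# Chunked PCA
# ---------------------------------------------------------------------------


def chunked_pca(
    features: np.ndarray,
    n_components: int,
    chunk_size: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Incremental PCA fitted over sequential row chunks.

    Returns ``(reduced, explained_variance_ratio)``.  Each fitting chunk
    must contain at least ``n_components`` rows, so a short trailing chunk
    is folded into its predecessor.  The result is deterministic for a
    fixed seed and chunk order; with a single chunk it coincides with
    full-batch PCA up to per-component sign.
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if chunk_size < n_components:
        raise RoDatasetError("chunk_size must be >= n_components")
    if n_components > min(p, n):
        raise RoDatasetError("n_components exceeds the data dimensions")
    ipca = IncrementalPCA(n_components=n_components)
    bounds = list(range(0, n, chunk_size)) + [n]
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < n_components:
        bounds.pop(-2)  # fold the short tail into the previous chunk
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ipca.partial_fit(X[lo:hi])
    return ipca.transform(X), ipca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Embedder backends (narrow interface)
# ---------------------------------------------------------------------------


def _fit_embedding(
    method: str, data: np.ndarray, precomputed: bool, seed: int, params: Mapping
) -> np.ndarray:
    params = dict(params)
    n = data.shape[0]
    if method == "pca":
        if precomputed:
            raise RoDatasetError("the pca embedder needs feature vectors, not distances")
        model = PCA(n_components=2, svd_solver="full", random_state=seed)
        return model.fit_transform(data)
    if method == "tsne":
        from sklearn.manifold import TSNE

        params.setdefault("perplexity", min(30.0, max(2.0, (n - 1) / 3.0)))
        tsne = TSNE(
            n_components=2,
            metric="precomputed" if precomputed else "euclidean",
            init="random" if precomputed else "pca",
            random_state=seed,
            **params,
        )
        return tsne.fit_transform(data)
    if method == "umap":
        import umap

        params.setdefault("n_neighbors", int(min(15, max(2, n - 1))))
        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed" if precomputed else "euclidean",
            random_state=seed,
            **params,
        )
        return reducer.fit_transform(data)
    raise RoDatasetError(f"unknown projection method {method!r}")


def project(
    dataset: CampaignDataset,
    config: ProjectionConfig,
    distance_matrix: np.ndarray | None = None,
) -> Embedding:
    """Project all rows of a dataset to 2-D.

    For ``metric="precomputed"`` a distance matrix must be supplied; for
    ``metric="gower"``/``"jaccard"`` it is computed here (weighted) and fed
    to the embedder as precomputed distances.  For ``metric="euclidean"``
    the encoded numeric features (min-max scaled, weight-scaled) go through
    an optional chunked-PCA pre-reduction before the embedder.
    """
    if config.metric == "precomputed" or config.metric in ("gower", "jaccard"):
        if config.method == "pca":
            raise RoDatasetError("the pca embedder needs feature vectors, not distances")
        if config.metric == "precomputed":
            if distance_matrix is None:
                raise RoDatasetError("metric='precomputed' requires a distance matrix")
            D = np.asarray(distance_matrix, dtype=float)
        else:
            D = _dist.pairwise_distances(
                dataset,
                metric=config.metric,
                weights=config.weights,
                categorical_mode=config.categorical_mode,
            )
        if D.shape != (len(dataset.rows), len(dataset.rows)):
            raise RoDatasetError("distance matrix shape does not match the dataset")
        coords = _fit_embedding(config.method, D, True, config.seed, config.method_params)
    else:
        fm = _dist.encode_features(
            dataset, weights=config.weights, categorical_mode=config.categorical_mode
        )
        if fm.cat.shape[1]:
            raise RoDatasetError(
                "euclidean projection requires an all-numeric encoding "
                "(use categorical_mode='descriptors' or metric='gower')"
            )
        X = _dist._minmax(fm.num, fm.num_ranges) * np.sqrt(fm.num_weights)
        if X.shape[1] > PCA_PREREDUCTION_THRESHOLD:
            n_comp = min(config.pca_components, X.shape[0], X.shape[1])
            X, _ = chunked_pca(X, n_comp, config.chunk_size, config.seed)
        coords = _fit_embedding(config.method, X, False, config.seed, config.method_params)
    return Embedding(np.asarray(coords, dtype=float), config)


# ---------------------------------------------------------------------------
# Overlap removal
# ---------------------------------------------------------------------------


def _overlap_pairs(coords: np.ndarray, min_dist: float) -> int:
    """Count point pairs closer than min_dist via a uniform grid."""
    cells: dict[tuple[int, int], list[int]] = {}
    inv = 1.0 / min_dist
    for i, (x, y) in enumerate(coords):
        cells.setdefault((int(np.floor(x * inv)), int(np.floor(y * inv))), []).append(i)
    count = 0
    for (cx, cy), members in cells.items():
        neigh = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                neigh.extend(cells.get((cx + dx, cy + dy), []))
        for i in members:
            for j in neigh:
                if j > i and np.hypot(*(coords[i] - coords[j])) < min_dist:
                    count += 1
    return count


def remove_overlaps(
    embedding: Embedding,
    min_dist: float,
    max_iter: int = 20,
    displacement_cap: float | None = None,
) -> Embedding:
    """Declutter an embedding by iterative pairwise repulsion.

    Point pairs closer than ``min_dist`` are pushed apart symmetrically on a
    spatial grid, at most ``max_iter`` sweeps; no point moves further than
    ``displacement_cap`` (default ``4 * min_dist``) from its original
    position.  Coincident points are first separated along deterministic
    directions (angle 2*pi*rank/n by stable row index).  Best-effort: the
    returned layout never has more close pairs than the input.
    """
    if min_dist <= 0:
        raise RoDatasetError("min_dist must be positive")
    cap = displacement_cap if displacement_cap is not None else 4.0 * min_dist
    orig = embedding.coords.copy()
    pos = orig.copy()
    n = len(pos)
    inv = 1.0 / min_dist

    before = _overlap_pairs(orig, min_dist)
    if before == 0:
        return Embedding(orig, embedding.config)

    for _ in range(max_iter):
        moved = False
        cells: dict[tuple[int, int], list[int]] = {}
        for i, (x, y) in enumerate(pos):
            cells.setdefault((int(np.floor(x * inv)), int(np.floor(y * inv))), []).append(i)
        disp = np.zeros_like(pos)
        for (cx, cy), members in cells.items():
            neigh = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    neigh.extend(cells.get((cx + dx, cy + dy), []))
            for i in members:
                for j in neigh:
                    if j <= i:
                        continue
                    delta = pos[i] - pos[j]
                    d = float(np.hypot(*delta))
                    if d >= min_dist:
                        continue
                    if d < 1e-12:  # coincident: deterministic tie-break direction
                        ang_i = 2.0 * np.pi * i / n
                        ang_j = 2.0 * np.pi * j / n
                        disp[i] += 0.55 * min_dist * np.array([np.cos(ang_i), np.sin(ang_i)])
                        disp[j] += 0.55 * min_dist * np.array([np.cos(ang_j), np.sin(ang_j)])
                    else:
                        push = 0.5 * (min_dist - d) * delta / d
                        disp[i] += push * 1.05
                        disp[j] -= push * 1.05
                    moved = True
        if not moved:
            break
        pos = pos + disp
        # enforce the displacement cap relative to the original layout
        off = pos - orig
        norm = np.hypot(off[:, 0], off[:, 1])
        over = norm > cap
        if np.any(over):
            pos[over] = orig[over] + off[over] * (cap / norm[over])[:, None]

    after = _overlap_pairs(pos, min_dist)
    if after > before:  # never worse than the input
        return Embedding(orig, embedding.config)
    return Embedding(pos, embedding.config)
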