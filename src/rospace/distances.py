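"""Weighted similarity/distance computation for mixed-type experiments.

Candidate experiments mix categorical parameters (reagents, ligands, bases)
with numeric ones (temperature, concentration), so the workhorse metric is
Gower's similarity coefficient: range-normalized absolute difference for
numerics, match indicator for categoricals, weighted-averaged over the
features comparable on both rows.  Because downstream embedders take a
pre-computed matrix, custom per-feature weights can be applied here once
and respected by every projection method.

Numeric ranges are always computed on the FULL dataset, never on a filtered
subset, so distances are stable under filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ro_dataset import (
    CATEGORICAL,
    NUMERIC,
    CampaignDataset,
    RoDatasetError,
)

__all__ = [
    "FeatureMatrix",
    "encode_features",
    "gower_distance",
    "gower_matrix",
    "gower_cross",
    "pairwise_distances",
]

#: Above this row count, pairwise matrices are filled block-wise instead of
#: in one shot, to bound peak memory.
DENSE_ROW_LIMIT = 5_000
_BLOCK = 2_000


@dataclass
class FeatureMatrix:
    """Encoded experiment features split by kind.

    ``num`` holds numeric features (NaN = missing) with per-feature weights
    and full-dataset ranges; ``cat`` holds categorical features as label
    arrays (None/NaN = missing).
    """

    num: np.ndarray  # (n, p_num) float
    num_weights: np.ndarray
    num_ranges: np.ndarray
    num_names: list[str]
    cat: np.ndarray  # (n, p_cat) object
    cat_weights: np.ndarray
    cat_names: list[str]

    def __post_init__(self):
        if self.num.shape[1] != len(self.num_weights) or self.cat.shape[1] != len(
            self.cat_weights
        ):
            raise RoDatasetError("feature weights must align 1:1 with columns")
        if np.any(self.num_weights < 0) or np.any(self.cat_weights < 0):
            raise RoDatasetError("feature weights must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.num.shape[0]

    @property
    def n_features(self) -> int:
        return self.num.shape[1] + self.cat.shape[1]


def encode_features(
    dataset: CampaignDataset,
    weights: Mapping[str, float] | None = None,
    categorical_mode: str = "labels",
    include_descriptor_columns: bool = True,
) -> FeatureMatrix:
    """Encode a dataset's parameters (and linked descriptors) for distances.

    ``categorical_mode="labels"`` compares categorical parameters by
    match/mismatch; ``"descriptors"`` replaces a categorical parameter that
    carries per-level descriptor vectors with those vectors as a numeric
    block, splitting the parameter's weight uniformly over the block so its
    total influence is unchanged.  Descriptor-role columns already present
    in the table are appended as numeric features inheriting the linked
    parameter's weight.
    """
    if categorical_mode not in ("labels", "descriptors"):
        raise RoDatasetError(f"unknown categorical_mode {categorical_mode!r}")
    weights = dict(weights or {})
    num_cols, num_w, cat_cols, cat_w = [], [], [], []
    num_data, cat_data = [], []
    n = len(dataset.rows)

    for p in dataset.params:
        w = float(weights.get(p.name, p.weight))
        col = dataset.rows[p.name]
        if p.kind == NUMERIC:
            num_cols.append(p.name)
            num_w.append(w)
            num_data.append(np.asarray(col, dtype=float))
        elif categorical_mode == "descriptors" and p.descriptors:
            d = p.descriptor_length
            vecs = {k: np.atleast_1d(np.asarray(v, float)) for k, v in p.descriptors.items()}
            block = np.full((n, d), np.nan)
            for i, level in enumerate(col):
                if level in vecs:
                    block[i] = vecs[level]
            for j in range(d):
                num_cols.append(f"{p.name}[{j}]")
                num_w.append(w / d)
                num_data.append(block[:, j])
        else:
            cat_cols.append(p.name)
            cat_w.append(w)
            cat_data.append(np.asarray(col, dtype=object))

    if include_descriptor_columns:
        for name in dataset.columns_with_role("descriptor"):
            link = dataset.roles[name].parameter_link
            w = float(weights.get(name, weights.get(link, 1.0) if link else 1.0))
            num_cols.append(name)
            num_w.append(w)
            num_data.append(np.asarray(dataset.rows[name], dtype=float))

    num = np.column_stack(num_data) if num_data else np.empty((n, 0))
    cat = (
        np.column_stack(cat_data).astype(object) if cat_data else np.empty((n, 0), object)
    )
    with np.errstate(invalid="ignore"):
        ranges = (
            np.nanmax(num, axis=0) - np.nanmin(num, axis=0)
            if num.size
            else np.empty(0)
        )
    ranges = np.nan_to_num(ranges, nan=0.0)
    return FeatureMatrix(
        num=num,
        num_weights=np.asarray(num_w, float),
        num_ranges=ranges,
        num_names=num_cols,
        cat=cat,
        cat_weights=np.asarray(cat_w, float),
        cat_names=cat_cols,
    )


# ---------------------------------------------------------------------------
# Gower
# ---------------------------------------------------------------------------


def _cat_missing(block: np.ndarray) -> np.ndarray:
    miss = np.zeros(block.shape, bool)
    for j in range(block.shape[1]):
        col = block[:, j]
        miss[:, j] = [v is None or (isinstance(v, float) and np.isnan(v)) for v in col]
    return miss


def _gower_block(fm: FeatureMatrix, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Weighted Gower distances between two index sets; NaN-aware."""
    na, nb = len(rows_a), len(rows_b)
    S = np.zeros((na, nb))
    D = np.zeros((na, nb))
    for k in range(fm.num.shape[1]):
        w = fm.num_weights[k]
        if w == 0:
            continue
        a = fm.num[rows_a, k][:, None]
        b = fm.num[rows_b, k][None, :]
        present = ~np.isnan(a) & ~np.isnan(b)
        r = fm.num_ranges[k]
        if r > 0:
            sim = 1.0 - np.abs(a - b) / r
        else:
            sim = np.ones((na, nb))
        sim = np.where(present, sim, 0.0)
        S += w * sim
        D += w * present
    if fm.cat.shape[1]:
        miss = _cat_missing(fm.cat)
        for k in range(fm.cat.shape[1]):
            w = fm.cat_weights[k]
            if w == 0:
                continue
            a = fm.cat[rows_a, k][:, None]
            b = fm.cat[rows_b, k][None, :]
            present = ~miss[rows_a, k][:, None] & ~miss[rows_b, k][None, :]
            sim = (a == b) & present
            S += w * sim
            D += w * present
    if np.any(D == 0):
        raise RoDatasetError(
            "no comparable features with positive weight for some row pair"
        )
    return 1.0 - S / D


def gower_distance(a: int, b: int, fm: FeatureMatrix) -> float:
    """Gower distance in [0, 1] between rows ``a`` and ``b`` of ``fm``.

    Similarity s = sum_k w_k s_k / sum_k w_k d_k with s_k the per-feature
    similarity (1 - |a-b|/range for numerics, match indicator for
    categoricals) and d_k = 1 iff both values are present; distance = 1 - s.
    Missing values are simply excluded from the average.
    """
    return float(_gower_block(fm, np.array([a]), np.array([b]))[0, 0])


def gower_cross(fm: FeatureMatrix, rows_a, rows_b) -> np.ndarray:
    """Gower distance matrix between two row-index sets (for surrogates)."""
    return _gower_block(fm, np.asarray(rows_a), np.asarray(rows_b))


def gower_matrix(fm: FeatureMatrix) -> np.ndarray:
    """Full pairwise Gower distance matrix (symmetric, zero diagonal).

    Below ``DENSE_ROW_LIMIT`` rows the matrix is computed in one shot;
    larger inputs are filled block-wise with a fixed block size to bound
    peak memory.
    """
    n = fm.n_rows
    idx = np.arange(n)
    if n <= DENSE_ROW_LIMIT:
        out = _gower_block(fm, idx, idx)
    else:
        out = np.empty((n, n))
        for i0 in range(0, n, _BLOCK):
            for j0 in range(0, n, _BLOCK):
                ia = idx[i0 : i0 + _BLOCK]
                jb = idx[j0 : j0 + _BLOCK]
                out[i0 : i0 + _BLOCK, j0 : j0 + _BLOCK] = _gower_block(fm, ia, jb)
    np.fill_diagonal(out, 0.0)
    return np.clip((out + out.T) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Euclidean / Jaccard / dispatch
# ---------------------------------------------------------------------------


def _minmax(num: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    lo = np.nanmin(num, axis=0) if num.size else np.empty(0)
    scaled = num - lo
    nz = ranges > 0
    scaled[:, nz] = scaled[:, nz] / ranges[nz]
    scaled[:, ~nz] = 0.0
    return scaled


def _euclidean_matrix(fm: FeatureMatrix) -> np.ndarray:
    if fm.cat.shape[1]:
        raise RoDatasetError("euclidean metric requires all-numeric features")
    if np.isnan(fm.num[:, fm.num_weights > 0]).any():
        raise RoDatasetError("euclidean metric rejects missing values")
    X = _minmax(fm.num, fm.num_ranges) * np.sqrt(fm.num_weights)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.sqrt(np.clip(d2, 0.0, None))


def _jaccard_matrix(fm: FeatureMatrix) -> np.ndarray:
    if fm.num.shape[1]:
        raise RoDatasetError("jaccard metric requires all-categorical features")
    if _cat_missing(fm.cat).any():
        raise RoDatasetError("jaccard metric rejects missing values")
    n, p = fm.cat.shape
    # one-hot: each row activates exactly one level per feature, so
    # |A ∩ B| = #matching features and |A ∪ B| = 2p − matches
    matches = np.zeros((n, n))
    for k in range(p):
        col = fm.cat[:, k]
        matches += (col[:, None] == col[None, :]).astype(float)
    union = 2.0 * p - matches
    with np.errstate(invalid="ignore"):
        dist = 1.0 - matches / union
    return np.nan_to_num(dist, nan=0.0)


def pairwise_distances(
    dataset: CampaignDataset,
    metric: str = "gower",
    weights: Mapping[str, float] | None = None,
    categorical_mode: str = "labels",
) -> np.ndarray:
    """Pairwise distance matrix over a dataset's rows.

    ``gower`` handles mixed feature kinds; ``euclidean`` requires the
    encoding to be all-numeric (weighted, on min-max-scaled features);
    ``jaccard`` requires all-categorical features (one-hot set distance).
    The result is symmetric with a zero diagonal.
    """
    fm = encode_features(dataset, weights=weights, categorical_mode=categorical_mode)
    if metric == "gower":
        return gower_matrix(fm)
    if metric == "euclidean":
        return _euclidean_matrix(fm)
    if metric == "jaccard":
        return _jaccard_matrix(fm)
    raise RoDatasetError(f"unknown metric {metric!r}")
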