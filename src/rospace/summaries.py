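"""Temporal restructuring and group summary/difference statistics.

Per-cycle columns (prediction mean/std, acquisition, attributions) are
pivoted into experiments-by-cycles matrices for heatmap-style views, and a
per-experiment mean +/- k*std band tracks how the model's belief about one
candidate developed over the campaign.  Group summaries give per-parameter
level proportions (categoricals) and shared-edge histograms (numerics) for
a selected experiment set; group differences report the per-level change in
proportion between two sets, retaining only the large movers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ro_dataset import CATEGORICAL, NUMERIC, CampaignDataset, RoDatasetError

__all__ = [
    "TemporalMatrix",
    "PredictionBand",
    "GroupSummary",
    "GroupDifference",
    "temporal_matrix",
    "prediction_band",
    "group_summary",
    "group_difference",
    "parallel_coordinates_data",
    "DEFAULT_NUMERIC_BINS",
    "DEFAULT_DIFF_THRESHOLD",
]

#: Shared global equal-width bin count for numeric parameters in summaries.
DEFAULT_NUMERIC_BINS = 10

#: Minimum |delta proportion| for a level to be retained in a difference view.
DEFAULT_DIFF_THRESHOLD = 0.1

_FAMILIES = ("prediction_mean", "prediction_std", "acquisition", "attribution")


@dataclass
class TemporalMatrix:
    """Experiments x cycles matrix for one per-cycle column family."""

    family: str
    values: np.ndarray  # (n_rows, n_cycles)
    cycles: list[int]
    parameter: str | None = None  # set for the attribution family


@dataclass
class PredictionBand:
    """Per-cycle (lower, mean, upper) band for one experiment; width = k*std."""

    row_key: tuple
    cycles: list[int]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    k: float


@dataclass
class GroupSummary:
    """Per-parameter distributions of one experiment group.

    ``entries`` maps parameter name to a dict: categoricals carry
    ``proportions`` (level -> fraction of the group's non-missing rows);
    numerics carry ``edges``/``proportions`` for a histogram on bin edges
    shared across groups, plus ``quartiles``.
    """

    entries: dict[str, dict]
    n: int


@dataclass
class GroupDifference:
    """Per-level proportion changes between two groups.

    ``entries`` holds (parameter, level_or_bin, delta) for every level;
    ``retained`` is the subset with |delta| >= threshold, or the top-k by
    |delta|.  delta = proportion_in_A - proportion_in_B.
    """

    entries: list[tuple[str, object, float]]
    retained: list[tuple[str, object, float]]


# ---------------------------------------------------------------------------
# Temporal views
# ---------------------------------------------------------------------------


def temporal_matrix(
    dataset: CampaignDataset, family: str, parameter: str | None = None
) -> TemporalMatrix:
    """Assemble a family's per-cycle columns into one matrix, in cycle order.

    For the attribution family (one column per parameter per cycle) the
    linked ``parameter`` must be named.  Missing per-cycle cells stay NaN.
    """
    if family not in _FAMILIES:
        raise RoDatasetError(f"unknown per-cycle family {family!r}")
    if family == "attribution" and parameter is None:
        raise RoDatasetError("the attribution family requires a parameter name")
    cycles = list(range(dataset.n_cycles))
    cols, missing = [], []
    for c in cycles:
        found = dataset.columns_with_role(
            family, cycle=c, parameter_link=parameter if family == "attribution" else None
        )
        if not found:
            missing.append(c)
        else:
            cols.append(found[0])
    if missing or not cycles:
        raise RoDatasetError(
            f"family {family!r}"
            + (f" (parameter {parameter!r})" if parameter else "")
            + f" missing for cycles {missing or cycles}"
        )
    values = dataset.rows[cols].to_numpy(dtype=float)
    return TemporalMatrix(family=family, values=values, cycles=cycles, parameter=parameter)


def prediction_band(dataset: CampaignDataset, row_key: tuple, k: float = 1.0) -> PredictionBand:
    """Mean +/- k*std prediction band over cycles for one experiment."""
    if k <= 0:
        raise RoDatasetError("k must be positive")
    keys = dataset.row_keys()
    matches = [i for i, k in enumerate(keys) if k == tuple(row_key)]
    if not matches:
        raise RoDatasetError(f"unknown row key {row_key!r}")
    i = matches[0]
    mean = temporal_matrix(dataset, "prediction_mean").values[i]
    std = temporal_matrix(dataset, "prediction_std").values[i]
    return PredictionBand(
        row_key=tuple(row_key),
        cycles=list(range(dataset.n_cycles)),
        mean=mean,
        lower=mean - k * std,
        upper=mean + k * std,
        k=float(k),
    )


# ---------------------------------------------------------------------------
# Group summaries & differences
# ---------------------------------------------------------------------------


def _selection_mask(dataset: CampaignDataset, selection) -> np.ndarray:
    if isinstance(selection, np.ndarray) and selection.dtype == bool:
        if len(selection) != len(dataset.rows):
            raise RoDatasetError("boolean selection must align with dataset rows")
        return selection
    keys = dataset.row_keys()
    sel = {tuple(k) for k in selection}
    return np.asarray(keys.isin(sel))


def _global_edges(dataset: CampaignDataset, name: str, n_bins: int) -> np.ndarray:
    col = pd.to_numeric(dataset.rows[name], errors="coerce").dropna()
    lo, hi = float(col.min()), float(col.max())
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _param_distribution(
    dataset: CampaignDataset, mask: np.ndarray, n_bins: int
) -> dict[str, dict]:
    out = {}
    for p in dataset.params:
        col = dataset.rows.loc[mask, p.name]
        if p.kind == CATEGORICAL:
            valid = col.dropna()
            counts = valid.value_counts()
            total = counts.sum()
            props = {
                level: (float(counts.get(level, 0)) / total if total else 0.0)
                for level in p.values
            }
            out[p.name] = {"kind": CATEGORICAL, "proportions": props}
        else:
            edges = _global_edges(dataset, p.name, n_bins)
            vals = pd.to_numeric(col, errors="coerce").dropna().to_numpy()
            hist, _ = np.histogram(vals, bins=edges)
            total = hist.sum()
            props = hist / total if total else hist.astype(float)
            quart = (
                tuple(float(q) for q in np.percentile(vals, [25, 50, 75]))
                if len(vals)
                else (np.nan,) * 3
            )
            out[p.name] = {
                "kind": NUMERIC,
                "edges": edges,
                "proportions": props,
                "quartiles": quart,
            }
    return out


def group_summary(
    dataset: CampaignDataset, selection, n_bins: int = DEFAULT_NUMERIC_BINS
) -> GroupSummary:
    """Per-parameter value distributions of a selected experiment group.

    Numeric histogram edges are computed once on the full dataset, so
    summaries of different groups are directly comparable.
    """
    mask = _selection_mask(dataset, selection)
    if not mask.any():
        raise RoDatasetError("empty selection")
    return GroupSummary(entries=_param_distribution(dataset, mask, n_bins), n=int(mask.sum()))


def _bin_label(edges: np.ndarray, i: int) -> str:
    return f"[{edges[i]:g}, {edges[i + 1]:g}{']' if i == len(edges) - 2 else ')'}"


def group_difference(
    dataset: CampaignDataset,
    group_a,
    group_b,
    threshold: float | None = DEFAULT_DIFF_THRESHOLD,
    top_k: int | None = None,
    n_bins: int = DEFAULT_NUMERIC_BINS,
) -> GroupDifference:
    """Per-level proportion changes between two experiment groups.

    delta = proportion_A - proportion_B per categorical level (or shared
    numeric bin); the retained subset keeps |delta| >= threshold, or the
    top-k by |delta| when ``top_k`` is given.  Antisymmetric:
    diff(A, B) = -diff(B, A) entrywise.  Overlapping groups are allowed but
    warned about; empty groups are an error.
    """
    mask_a = _selection_mask(dataset, group_a)
    mask_b = _selection_mask(dataset, group_b)
    if not mask_a.any() or not mask_b.any():
        raise RoDatasetError("both groups must be non-empty")
    if (mask_a & mask_b).any():
        warnings.warn("group_difference: groups overlap", stacklevel=2)
    dist_a = _param_distribution(dataset, mask_a, n_bins)
    dist_b = _param_distribution(dataset, mask_b, n_bins)
    entries: list[tuple[str, object, float]] = []
    for p in dataset.params:
        da, db = dist_a[p.name], dist_b[p.name]
        if da["kind"] == CATEGORICAL:
            for level in p.values:
                entries.append(
                    (p.name, level, da["proportions"][level] - db["proportions"][level])
                )
        else:
            edges = da["edges"]
            for i, (pa, pb) in enumerate(zip(da["proportions"], db["proportions"])):
                entries.append((p.name, _bin_label(edges, i), float(pa - pb)))
    if top_k is not None:
        retained = sorted(entries, key=lambda e: -abs(e[2]))[:top_k]
    else:
        tau = DEFAULT_DIFF_THRESHOLD if threshold is None else threshold
        retained = [e for e in entries if abs(e[2]) >= tau]
    return GroupDifference(entries=entries, retained=retained)


# ---------------------------------------------------------------------------
# Parallel coordinates
# ---------------------------------------------------------------------------


def parallel_coordinates_data(
    dataset: CampaignDataset, selection, axes: Sequence[str]
) -> pd.DataFrame:
    """Axis positions in [0, 1] per row for a parallel-coordinates plot.

    Categorical levels sit at fixed ordinal slots (declaration order);
    numerics are min-max scaled over the full dataset.  ``highlight`` flags
    membership in the selection.  Pure data preparation — no rendering.
    """
    by_name = {p.name: p for p in dataset.params}
    for ax in axes:
        if ax not in by_name:
            raise RoDatasetError(f"unknown axis {ax!r}")
    mask = _selection_mask(dataset, selection) if selection is not None else np.zeros(
        len(dataset.rows), bool
    )
    out = pd.DataFrame(index=dataset.rows.index)
    for ax in axes:
        p = by_name[ax]
        col = dataset.rows[ax]
        if p.kind == CATEGORICAL:
            slots = {level: i for i, level in enumerate(p.values)}
            denom = max(len(p.values) - 1, 1)
            out[ax] = [slots.get(v, np.nan) / denom for v in col]
        else:
            vals = pd.to_numeric(col, errors="coerce")
            lo, hi = float(min(p.values)), float(max(p.values))
            out[ax] = (vals - lo) / (hi - lo) if hi > lo else 0.0
    out["highlight"] = mask
    return out
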