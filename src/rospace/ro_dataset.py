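"""Reaction-optimization campaign data model.

A campaign dataset is the full combinatorial table of candidate experiments:
one row per combination of parameter values, with optional measured targets,
the cycle each measurement was taken in, and per-cycle model outputs
(prediction mean/std, acquisition value, per-parameter attributions).

Datasets travel as plain CSV.  Column roles are declared with a brace
modifier appended to the column name, e.g. ``yield{measured}`` or
``pred{pred,c=3}``; unmodified columns are optimization parameters.  The
grammar is defined by :class:`DialectConfig` and can be swapped out via an
adapter hook for alternative dialects.
"""

from __future__ import annotations

import io
import itertools
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "ColumnRole",
    "CampaignDataset",
    "FilterSpec",
    "DialectConfig",
    "RoDatasetError",
    "build_parameter_space",
    "parse_dataset",
    "write_dataset",
    "apply_filter",
    "measured_subset",
    "load_config",
    "MAX_SPACE_ROWS",
    "DEFAULT_CHUNK_SIZE",
]

#: Hard cap on enumerated combinatorial spaces (guards accidental memory
#: blow-ups on large factorial designs); overridable per call.
MAX_SPACE_ROWS = 5_000_000

#: Default number of CSV rows held resident while parsing.
DEFAULT_CHUNK_SIZE = 100_000

CATEGORICAL = "categorical"
NUMERIC = "numeric"

#: Per-cycle column families, in the order the simulator emits them.
PER_CYCLE_ROLES = ("prediction_mean", "prediction_std", "acquisition", "attribution")


class RoDatasetError(ValueError):
    """Raised for malformed specs, dialect violations, or invariant breaks."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSpec:
    """One optimization parameter.

    Parameters
    ----------
    name
        Column name of the parameter.
    kind
        ``"categorical"`` (labels) or ``"numeric"`` (finite set of numbers,
        e.g. temperatures screened).
    values
        Ordered, unique allowed levels.
    descriptors
        Optional map from level to a fixed-length numeric vector (e.g.
        molecular descriptors of the compound a label denotes).
    weight
        Relative importance of this parameter in distance/projection
        computations; non-negative, default 1.
    """

    name: str
    kind: str
    values: tuple
    descriptors: Mapping | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in (CATEGORICAL, NUMERIC):
            raise RoDatasetError(f"parameter {self.name!r}: unknown kind {self.kind!r}")
        values = tuple(self.values)
        if not values:
            raise RoDatasetError(f"parameter {self.name!r} has an empty values list")
        if len(set(values)) != len(values):
            raise RoDatasetError(f"parameter {self.name!r} has duplicate values")
        if self.kind == NUMERIC:
            try:
                values = tuple(float(v) for v in values)
            except (TypeError, ValueError) as exc:
                raise RoDatasetError(
                    f"parameter {self.name!r} is numeric but has non-numeric values"
                ) from exc
        object.__setattr__(self, "values", values)
        if self.weight < 0:
            raise RoDatasetError(f"parameter {self.name!r}: weight must be >= 0")
        if self.descriptors is not None:
            lengths = {len(np.atleast_1d(v)) for v in self.descriptors.values()}
            if len(lengths) > 1:
                raise RoDatasetError(
                    f"parameter {self.name!r}: descriptor vectors have unequal lengths"
                )
            missing = [v for v in values if v not in self.descriptors]
            if missing:
                raise RoDatasetError(
                    f"parameter {self.name!r}: descriptors missing for levels {missing}"
                )

    @property
    def descriptor_length(self) -> int:
        if not self.descriptors:
            return 0
        return len(np.atleast_1d(next(iter(self.descriptors.values()))))


@dataclass(frozen=True)
class ColumnRole:
    """Role tag of one dataset column.

    ``cycle`` is required for per-cycle roles (prediction_mean,
    prediction_std, acquisition, attribution); ``parameter_link`` is required
    for attribution and descriptor columns.
    """

    role: str
    cycle: int | None = None
    parameter_link: str | None = None

    _ROLES = (
        "parameter",
        "descriptor",
        "measured_target",
        "cycle_index",
        "prediction_mean",
        "prediction_std",
        "acquisition",
        "attribution",
        "smiles",
        "other",
    )

    def __post_init__(self):
        if self.role not in self._ROLES:
            raise RoDatasetError(f"unknown column role {self.role!r}")
        if self.role in PER_CYCLE_ROLES:
            if self.cycle is None or self.cycle < 0:
                raise RoDatasetError(f"role {self.role!r} requires a cycle index >= 0")
        if self.role == "attribution" and not self.parameter_link:
            raise RoDatasetError("attribution columns require a parameter link")


@dataclass(frozen=True)
class FilterSpec:
    """Row filter: per-column predicates plus explicit exception keys.

    ``predicates`` maps a column name to either a membership set (categorical)
    or a closed ``(lo, hi)`` interval (numeric).  ``exceptions`` are row keys
    forced into the result even when the predicates exclude them — the
    mechanism that lets an analyst keep a handful of experiments visible
    outside the filtered region.
    """

    predicates: Mapping = field(default_factory=dict)
    exceptions: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "predicates", dict(self.predicates))
        object.__setattr__(self, "exceptions", frozenset(self.exceptions))


@dataclass(frozen=True)
class DialectConfig:
    """CSV column-modifier grammar.

    The default grammar appends ``{modifier[,key=value]...}`` to a column
    name: ``{measured}``, ``{cycle}``, ``{pred,c=N}``, ``{pred_std,c=N}``,
    ``{acq,c=N}``, ``{attr,c=N,p=PARAM}``, ``{desc,p=PARAM}``,
    ``{smiles,p=PARAM}``, ``{meta}``.  ``adapter`` (column name ->
    ColumnRole | None) is consulted first, allowing alternative dialects.
    """

    modifier_map: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_MODIFIERS)
    )
    adapter: Callable[[str], ColumnRole | None] | None = None

    def classify(self, column: str) -> ColumnRole:
        if self.adapter is not None:
            role = self.adapter(column)
            if role is not None:
                return role
        m = _MODIFIER_RE.search(column)
        if m is None:
            return ColumnRole("parameter")
        parts = [p.strip() for p in m.group(1).split(",")]
        keyword, opts = parts[0], parts[1:]
        base = column[: m.start()].strip()
        # convenience: "cycle{measured}" tags the cycle column of the
        # measured family, equivalent to "cycle{cycle}"
        if keyword == "measured" and base.lower() == "cycle":
            keyword = "cycle"
        role_name = self.modifier_map.get(keyword)
        if role_name is None:
            raise RoDatasetError(f"column {column!r}: unknown modifier {keyword!r}")
        cycle = None
        link = None
        for opt in opts:
            if "=" not in opt:
                raise RoDatasetError(f"column {column!r}: malformed option {opt!r}")
            key, _, val = opt.partition("=")
            if key == "c":
                try:
                    cycle = int(val)
                except ValueError as exc:
                    raise RoDatasetError(
                        f"column {column!r}: unparseable cycle suffix {val!r}"
                    ) from exc
            elif key == "p":
                link = val
            else:
                raise RoDatasetError(f"column {column!r}: unknown option key {key!r}")
        return ColumnRole(role_name, cycle=cycle, parameter_link=link)


_DEFAULT_MODIFIERS = {
    "measured": "measured_target",
    "cycle": "cycle_index",
    "pred": "prediction_mean",
    "pred_std": "prediction_std",
    "acq": "acquisition",
    "attr": "attribution",
    "desc": "descriptor",
    "smiles": "smiles",
    "meta": "other",
}

_MODIFIER_RE = re.compile(r"\{([^{}]*)\}\s*$")

_ROLE_TO_MODIFIER = {v: k for k, v in _DEFAULT_MODIFIERS.items()}


def column_name_for(base: str, role: ColumnRole) -> str:
    """Render a dialect column name for a role (inverse of classify)."""
    if role.role == "parameter":
        return base
    mod = _ROLE_TO_MODIFIER[role.role]
    parts = [mod]
    if role.cycle is not None:
        parts.append(f"c={role.cycle}")
    if role.parameter_link is not None:
        parts.append(f"p={role.parameter_link}")
    return f"{base}{{{','.join(parts)}}}"


@dataclass
class CampaignDataset:
    """The full combinatorial table plus role-tagged columns.

    ``rows`` keeps the original (dialect) column names; ``roles`` maps each
    column name to its :class:`ColumnRole`.  Row identity is the tuple of
    parameter values in declaration order.
    """

    params: list[ParameterSpec]
    rows: pd.DataFrame
    roles: dict[str, ColumnRole]
    n_cycles: int = 0

    # -- column lookup -----------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def columns_with_role(
        self, role: str, cycle: int | None = None, parameter_link: str | None = None
    ) -> list[str]:
        out = []
        for name, r in self.roles.items():
            if r.role != role:
                continue
            if cycle is not None and r.cycle != cycle:
                continue
            if parameter_link is not None and r.parameter_link != parameter_link:
                continue
            out.append(name)
        return out

    def single_column(self, role: str, **kw) -> str | None:
        cols = self.columns_with_role(role, **kw)
        if len(cols) > 1:
            raise RoDatasetError(f"multiple columns with role {role!r}: {cols}")
        return cols[0] if cols else None

    @property
    def measured_column(self) -> str | None:
        return self.single_column("measured_target")

    @property
    def cycle_column(self) -> str | None:
        return self.single_column("cycle_index")

    # -- row identity ------------------------------------------------------

    def row_keys(self) -> pd.Index:
        if not self.params:
            return pd.Index([()] * len(self.rows), tupleize_cols=False)
        return pd.Index(
            list(map(tuple, self.rows[self.param_names].itertuples(index=False))),
            tupleize_cols=False,
        )

    def key_of(self, i: int) -> tuple:
        return tuple(self.rows.iloc[i][self.param_names])

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check all dataset invariants; raise RoDatasetError on the first break."""
        keys = self.row_keys()
        if keys.has_duplicates:
            dup = keys[keys.duplicated()][0]
            raise RoDatasetError(f"duplicate parameter assignment: {dup!r}")
        mcol, ccol = self.measured_column, self.cycle_column
        if (mcol is None) != (ccol is None):
            raise RoDatasetError("measured target and cycle index must co-occur")
        if mcol is not None:
            measured = self.rows[mcol].notna()
            cycled = self.rows[ccol].notna()
            if not measured.equals(cycled):
                raise RoDatasetError(
                    "rows must have a cycle index iff they have a measured value"
                )
            cycles = self.rows.loc[cycled, ccol]
            if len(cycles) and (
                (cycles < 0).any() or (cycles > self.n_cycles - 1).any()
            ):
                raise RoDatasetError(
                    f"cycle indices outside 0..{self.n_cycles - 1}"
                )
        for fam in PER_CYCLE_ROLES:
            cols = self.columns_with_role(fam)
            if not cols:
                continue
            have = {self.roles[c].cycle for c in cols}
            want = set(range(self.n_cycles))
            if not want <= have:
                raise RoDatasetError(
                    f"family {fam!r} missing cycles {sorted(want - have)}"
                )

    def copy(self) -> "CampaignDataset":
        return CampaignDataset(
            list(self.params), self.rows.copy(), dict(self.roles), self.n_cycles
        )

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Space construction
# ---------------------------------------------------------------------------


def build_parameter_space(
    params: Sequence[ParameterSpec], max_rows: int = MAX_SPACE_ROWS
) -> CampaignDataset:
    """Enumerate the full combinatorial parameter space.

    Returns a dataset with exactly ``prod(len(p.values))`` rows in
    lexicographic order (by parameter declaration order, then value order)
    and no measurement or per-cycle columns.  Zero parameters yield the
    single empty assignment.  Spaces larger than ``max_rows`` are refused:
    combinatorial growth is the defining scaling problem of reaction
    optimization (three parameters at five levels already give 5^3 = 125
    candidate experiments) and a runaway product should fail loudly.
    """
    params = list(params)
    for p in params:
        if not isinstance(p, ParameterSpec):
            raise RoDatasetError(f"expected ParameterSpec, got {type(p).__name__}")
    n_rows = math.prod(len(p.values) for p in params)
    if n_rows > max_rows:
        raise RoDatasetError(
            f"parameter space has {n_rows} rows, exceeding the cap of {max_rows}"
        )
    if params:
        rows = pd.DataFrame(
            itertools.product(*(p.values for p in params)),
            columns=[p.name for p in params],
        )
    else:
        rows = pd.DataFrame(index=[0])
    roles = {p.name: ColumnRole("parameter") for p in params}
    ds = CampaignDataset(params, rows, roles, n_cycles=0)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# CSV parsing / writing
# ---------------------------------------------------------------------------


def _split_header(line: str) -> list[str]:
    """Split a header row on commas outside quotes and brace groups."""
    fields, buf = [], []
    in_quotes = False
    depth = 0
    i = 0
    while i < len(line):
        ch = line[i]
        if in_quotes:
            if ch == '"':
                if i + 1 < len(line) and line[i + 1] == '"':
                    buf.append('"')
                    i += 1
                else:
                    in_quotes = False
            else:
                buf.append(ch)
        elif ch == '"':
            in_quotes = True
        elif ch == "{":
            depth += 1
            buf.append(ch)
        elif ch == "}":
            depth = max(depth - 1, 0)
            buf.append(ch)
        elif ch == "," and depth == 0:
            fields.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
        i += 1
    fields.append("".join(buf).strip())
    if len(set(fields)) != len(fields):
        raise RoDatasetError("duplicate column names in header")
    return fields


def _infer_kind(series: pd.Series, name: str, overrides: Mapping[str, str]) -> str:
    if name in overrides:
        return overrides[name]
    values = series.dropna()
    converted = pd.to_numeric(values, errors="coerce")
    return NUMERIC if converted.notna().all() and len(values) else CATEGORICAL


def parse_dataset(
    csv_source,
    dialect: DialectConfig | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    kind_overrides: Mapping[str, str] | None = None,
) -> CampaignDataset:
    """Parse a campaign CSV into a :class:`CampaignDataset`.

    Reading is chunked so at most ``chunk_size`` rows are resident during
    the scan; the result is independent of ``chunk_size``.  Columns are
    classified by the dialect's modifier grammar; unmodified columns become
    parameters whose kind (numeric vs categorical) is inferred from
    parseability, overridable via ``kind_overrides``.
    """
    dialect = dialect or DialectConfig()
    kind_overrides = dict(kind_overrides or {})
    if chunk_size < 1:
        raise RoDatasetError("chunk_size must be >= 1")

    if isinstance(csv_source, (str, Path)):
        opener = lambda: open(csv_source, "r", newline="")  # noqa: E731
    else:  # file-like: buffer the text once so we can re-scan
        text = csv_source.read()
        opener = lambda: io.StringIO(text)  # noqa: E731

    with opener() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise RoDatasetError("missing CSV header row")
    # Tokenize the header ourselves: modifier options contain commas
    # (e.g. "pred{pred,c=0}"), which are legal both bare and RFC-4180 quoted.
    columns = _split_header(header_line.rstrip("\r\n"))

    with opener() as fh:
        reader = pd.read_csv(
            fh,
            chunksize=chunk_size,
            dtype=str,
            skip_blank_lines=True,
            header=None,
            skiprows=1,
            names=columns,
        )
        chunks = [chunk for chunk in reader]
    if chunks:
        rows = pd.concat(chunks, ignore_index=True)
    else:
        rows = pd.DataFrame({c: pd.Series(dtype=str) for c in columns})

    roles = {c: dialect.classify(c) for c in rows.columns}

    # Coerce non-parameter numeric columns.
    for col, role in roles.items():
        if role.role in ("measured_target", "cycle_index", "descriptor") or (
            role.role in PER_CYCLE_ROLES
        ):
            rows[col] = pd.to_numeric(rows[col], errors="coerce")
    ccol = next((c for c, r in roles.items() if r.role == "cycle_index"), None)
    if ccol is not None:
        rows[ccol] = rows[ccol].astype("Int64").astype("float64")

    params = []
    for col, role in roles.items():
        if role.role != "parameter":
            continue
        kind = _infer_kind(rows[col], col, kind_overrides)
        if kind == NUMERIC:
            rows[col] = pd.to_numeric(rows[col])
            values = tuple(sorted(rows[col].dropna().unique()))
        else:
            values = tuple(dict.fromkeys(rows[col].dropna()))
        params.append(ParameterSpec(col, kind, values))

    per_cycle = [r.cycle for r in roles.values() if r.role in PER_CYCLE_ROLES]
    if per_cycle:
        n_cycles = max(per_cycle) + 1
    elif ccol is not None and rows[ccol].notna().any():
        n_cycles = int(rows[ccol].max()) + 1
    else:
        n_cycles = 0

    ds = CampaignDataset(params, rows, roles, n_cycles=n_cycles)
    ds.validate()
    return ds


def write_dataset(dataset: CampaignDataset, path) -> None:
    """Write a dataset back to dialect CSV (RFC-4180, full float precision).

    Empty cells encode missing values; ``parse_dataset`` round-trips the
    result to numeric equality within 1e-12.
    """
    out = dataset.rows.copy()
    ccol = dataset.cycle_column
    if ccol is not None:
        out[ccol] = out[ccol].astype("Int64")
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Filtering & temporal subsetting
# ---------------------------------------------------------------------------


def apply_filter(dataset: CampaignDataset, spec: FilterSpec) -> CampaignDataset:
    """Select rows satisfying all predicates, plus the exception rows.

    Exceptions are row keys (tuples of parameter values) included regardless
    of the predicates.  Row order, columns and roles are preserved; an empty
    predicate list selects every row.
    """
    mask = pd.Series(True, index=dataset.rows.index)
    for col, cond in spec.predicates.items():
        if col not in dataset.rows.columns:
            raise RoDatasetError(f"filter predicate on unknown column {col!r}")
        series = dataset.rows[col]
        if isinstance(cond, (set, frozenset, list)):
            mask &= series.isin(list(cond))
        else:
            lo, hi = cond
            mask &= (series >= lo) & (series <= hi)
    if spec.exceptions:
        keys = dataset.row_keys()
        valid = set(keys)
        bad = set(spec.exceptions) - valid
        if bad:
            raise RoDatasetError(f"filter exceptions are not valid row keys: {bad}")
        mask |= pd.Series(keys.isin(spec.exceptions), index=dataset.rows.index)
    result = dataset.copy()
    result.rows = dataset.rows[mask.to_numpy()].copy()
    return result


def measured_subset(dataset: CampaignDataset, up_to_cycle: int) -> CampaignDataset:
    """Rows measured at cycle ``up_to_cycle`` or earlier (time-slider data)."""
    if not 0 <= up_to_cycle < max(dataset.n_cycles, 1):
        raise RoDatasetError(
            f"up_to_cycle {up_to_cycle} outside 0..{dataset.n_cycles - 1}"
        )
    result = dataset.copy()
    ccol = dataset.cycle_column
    if ccol is None:
        result.rows = dataset.rows.iloc[0:0].copy()
        return result
    mask = dataset.rows[ccol].notna() & (dataset.rows[ccol] <= up_to_cycle)
    if dataset.measured_column is not None:
        mask &= dataset.rows[dataset.measured_column].notna()
    result.rows = dataset.rows[mask.to_numpy()].copy()
    return result


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a TOML or JSON config (chunk_size, max_space_rows, overrides)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import tomllib

    return tomllib.loads(text)
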