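"""Synthetic AI-guided reaction-optimization campaigns.

Generates complete campaign tables in the package's CSV dialect: a ground
truth yield surface with main effects and pairwise interactions over the
combinatorial space, a surrogate model with predictive uncertainty, an
acquisition function driving batch selection over cycles, and per-parameter
occlusion attributions — so every analysis stage can be exercised on data
whose structure is known by construction.

The surrogate is a Nadaraya-Watson kernel regression over Gower distances:
a deliberately dependency-light emulation of the Gaussian-process drivers
used in real campaigns.  It honors the two semantics downstream analyses
rely on — predictions near measured experiments are confident, and
uncertainty at a measured point shrinks and stays low — without reproducing
any particular GP implementation.  Attributions are occlusion-based (how
much does the actual level raise the prediction relative to the alternative
levels), exact and fast on categorical spaces, emitted in the same
per-cycle per-parameter column schema SHAP values would occupy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import distances as _dist
from .ro_dataset import (
    CATEGORICAL,
    NUMERIC,
    CampaignDataset,
    ColumnRole,
    ParameterSpec,
    RoDatasetError,
    build_parameter_space,
    column_name_for,
)

__all__ = [
    "TruthModel",
    "SurrogateModel",
    "CampaignConfig",
    "surrogate_predict",
    "expected_improvement",
    "occlusion_attribution",
    "run_campaign",
    "preset_params",
    "planted_truth",
    "simulate_campaign",
    "PRESETS",
]

ACQUISITIONS = ("expected_improvement", "greedy_mean", "max_uncertainty")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthModel:
    """Additive + pairwise-interaction yield surface, clamped to [0, 100] %.

    yield = clamp(base + sum of main effects + sum of interaction effects
    + Normal(0, noise_sd^2), 0, 100).  Interactions are keyed by frozensets
    of (parameter, level) pairs, realizing the "only particular combinations
    work" structure typical of reaction optimization.
    """

    base: float = 30.0
    main_effects: Mapping[str, Mapping] = field(default_factory=dict)
    interactions: Mapping = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise RoDatasetError("noise_sd must be >= 0")

    def latent(self, rows: pd.DataFrame) -> np.ndarray:
        """Noise-free yield surface before clamping."""
        y = np.full(len(rows), self.base, dtype=float)
        for pname, effects in self.main_effects.items():
            y += np.array([effects.get(v, 0.0) for v in rows[pname]])
        for key, effect in self.interactions.items():
            pairs = list(key)
            mask = np.ones(len(rows), bool)
            for pname, level in pairs:
                mask &= np.asarray(rows[pname] == level)
            y += effect * mask
        return y

    def sample(self, rows: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        y = self.latent(rows)
        if self.noise_sd > 0:
            y = y + rng.normal(0.0, self.noise_sd, size=len(rows))
        return np.clip(y, 0.0, 100.0)


# ---------------------------------------------------------------------------
# Surrogate
# ---------------------------------------------------------------------------


@dataclass
class SurrogateModel:
    """Kernel-regression surrogate with predictive uncertainty.

    Prediction at a query is the Gaussian-kernel weighted mean of measured
    yields (weights K(d/h) over Gower distances d), shrunk toward
    ``prior_mean`` with weight K(1); predictive sd is
    ``prior_sd * (1 - max_i K(d_i/h)) + floor_sd``, so it is near the floor
    at measured points and near the prior far from all data.  A query
    coinciding with a training point returns that measurement exactly.
    """

    fm: _dist.FeatureMatrix
    bandwidth: float = 0.25
    prior_mean: float = 50.0
    prior_sd: float = 25.0
    floor_sd: float = 1.0
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    train_y: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise RoDatasetError("bandwidth must be > 0")

    def fit(self, train_idx, train_y) -> "SurrogateModel":
        self.train_idx = np.asarray(train_idx, int)
        self.train_y = np.asarray(train_y, float)
        return self

    def predict(self, query_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) arrays for the queried rows (default: all rows)."""
        if query_idx is None:
            query_idx = np.arange(self.fm.n_rows)
        query_idx = np.asarray(query_idx, int)
        n = len(query_idx)
        if len(self.train_idx) == 0:
            return (
                np.full(n, self.prior_mean),
                np.full(n, self.prior_sd),
            )
        D = _dist.gower_cross(self.fm, query_idx, self.train_idx)
        return self._predict_from_distances(D)

    def _predict_from_distances(self, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        K = np.exp(-0.5 * (D / self.bandwidth) ** 2)
        w0 = math.exp(-0.5)  # prior weight: the kernel at unit argument, K(1)
        mean = (K @ self.train_y + w0 * self.prior_mean) / (K.sum(axis=1) + w0)
        kmax = K.max(axis=1)
        sd = self.prior_sd * (1.0 - kmax) + self.floor_sd
        # exact hits interpolate: return the measurement itself
        exact = D.min(axis=1) <= 1e-12
        if exact.any():
            nearest = D.argmin(axis=1)
            mean[exact] = self.train_y[nearest[exact]]
            sd[exact] = self.floor_sd
        return mean, sd


def surrogate_predict(model: SurrogateModel, experiment_index: int) -> tuple[float, float]:
    """(mean, sd) prediction for one experiment of the model's space."""
    mean, sd = model.predict(np.array([experiment_index]))
    return float(mean[0]), float(sd[0])


def expected_improvement(mean, sd, best_so_far: float) -> np.ndarray:
    """Expected improvement of a Normal(mean, sd) belief over the incumbent.

    EI = sd * (z * Phi(z) + phi(z)) with z = (mean - best)/sd; for sd = 0 it
    degenerates to max(mean - best, 0).  Vectorized and always >= 0.
    """
    scalar = np.isscalar(mean) and np.isscalar(sd)
    mean = np.atleast_1d(np.asarray(mean, float))
    sd = np.atleast_1d(np.asarray(sd, float))
    if np.any(sd < 0):
        raise RoDatasetError("sd must be >= 0")
    out = np.maximum(mean - best_so_far, 0.0)
    pos = sd > 0
    if np.any(pos):
        z = (mean[pos] - best_so_far) / sd[pos]
        out[pos] = sd[pos] * (z * norm.cdf(z) + norm.pdf(z))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Occlusion attributions
# ---------------------------------------------------------------------------


def _occlusion_all(
    model: SurrogateModel, space: CampaignDataset, parameter: str, base_mean: np.ndarray
) -> np.ndarray:
    """Occlusion attribution of one parameter for every row of the space."""
    spec = next((p for p in space.params if p.name == parameter), None)
    if spec is None:
        raise RoDatasetError(f"unknown parameter {parameter!r}")
    if len(spec.values) < 2 or len(model.train_idx) == 0:
        return np.zeros(len(space.rows))
    preds = {}
    for level in spec.values:
        # re-encode with the parameter pinned to one level; ranges/weights as-is
        rows = space.rows.copy()
        rows[parameter] = [level] * len(rows)
        alt = CampaignDataset(space.params, rows, dict(space.roles), space.n_cycles)
        fm_alt = _dist.encode_features(alt)
        fm_alt.num_ranges = model.fm.num_ranges  # keep full-space normalization
        D = _dist._gower_block(
            _merge_for_cross(fm_alt, model.fm),
            np.arange(len(rows)),
            len(rows) + model.train_idx,
        )
        preds[level] = model._predict_from_distances(D)[0]
    actual = space.rows[parameter].to_numpy()
    attr = np.zeros(len(actual))
    for i, lvl in enumerate(actual):
        others = [preds[v][i] for v in spec.values if v != lvl]
        attr[i] = base_mean[i] - float(np.mean(others))
    return attr


def _merge_for_cross(fm_a: _dist.FeatureMatrix, fm_b: _dist.FeatureMatrix):
    """Stack two encodings so gower cross-distances can be computed."""
    return _dist.FeatureMatrix(
        num=np.vstack([fm_a.num, fm_b.num]),
        num_weights=fm_b.num_weights,
        num_ranges=fm_b.num_ranges,
        num_names=fm_b.num_names,
        cat=np.vstack([fm_a.cat, fm_b.cat]),
        cat_weights=fm_b.cat_weights,
        cat_names=fm_b.cat_names,
    )


def occlusion_attribution(
    model: SurrogateModel, space: CampaignDataset, experiment_index: int, parameter: str
) -> float:
    """How much the experiment's actual level of one parameter raises the
    prediction, relative to the uniform average over the other levels.

    Positive means the chosen level helps; a single-level parameter has
    attribution 0 by convention.
    """
    base_mean, _ = model.predict()
    attr = _occlusion_all(model, space, parameter, base_mean)
    return float(attr[experiment_index])


# ---------------------------------------------------------------------------
# Campaign loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to run a reproducible simulated campaign."""

    params: tuple
    truth: TruthModel
    n_cycles: int = 8
    batch_size: int = 5
    init_policy: str = "random"
    acquisition: str = "expected_improvement"
    seed: int = 0
    bandwidth: float = 0.25
    prior_mean: float = 50.0
    prior_sd: float = 25.0
    floor_sd: float = 1.0
    write_attributions: bool = True

    def __post_init__(self):
        if self.acquisition not in ACQUISITIONS:
            raise RoDatasetError(f"unknown acquisition {self.acquisition!r}")
        if self.init_policy != "random":
            raise RoDatasetError(f"unknown init policy {self.init_policy!r}")
        space = math.prod(len(p.values) for p in self.params)
        if self.batch_size * self.n_cycles > space:
            raise RoDatasetError(
                f"campaign needs {self.batch_size * self.n_cycles} experiments "
                f"but the space has only {space}"
            )


def run_campaign(config: CampaignConfig) -> CampaignDataset:
    """Simulate an AI-guided campaign over the full parameter space.

    Cycle 0 measures a seeded random batch.  Every cycle (including 0)
    first fits the surrogate on all measurements so far and writes
    prediction mean/std, acquisition, and per-parameter attribution columns
    for that cycle for ALL rows; later cycles then pick the top
    ``batch_size`` unmeasured rows by acquisition value (ties resolved by
    row order, which is lexicographic in the parameter values), measure
    them against the noisy truth, and record the cycle index.  All
    randomness flows from ``config.seed``, so campaigns are bitwise
    reproducible.
    """
    rng = np.random.default_rng(config.seed)
    space = build_parameter_space(list(config.params))
    n = len(space.rows)
    fm = _dist.encode_features(space)
    model = SurrogateModel(
        fm,
        bandwidth=config.bandwidth,
        prior_mean=config.prior_mean,
        prior_sd=config.prior_sd,
        floor_sd=config.floor_sd,
    )

    measured = np.full(n, np.nan)
    cycle_of = np.full(n, np.nan)
    new_cols: dict[str, np.ndarray] = {}
    roles = dict(space.roles)

    for c in range(config.n_cycles):
        done = ~np.isnan(measured)
        model.fit(np.flatnonzero(done), measured[done])
        mean, sd = model.predict()
        best = measured[done].max() if done.any() else config.prior_mean

        if config.acquisition == "expected_improvement":
            acq = expected_improvement(mean, sd, best)
        elif config.acquisition == "greedy_mean":
            acq = mean.copy()
        else:  # max_uncertainty
            acq = sd.copy()

        _add_cycle_columns(new_cols, roles, c, mean, sd, acq)
        if config.write_attributions:
            for p in space.params:
                attr = _occlusion_all(model, space, p.name, mean)
                name = column_name_for(f"attr_{p.name}", ColumnRole("attribution", c, p.name))
                new_cols[name] = attr
                roles[name] = ColumnRole("attribution", cycle=c, parameter_link=p.name)

        candidates = np.flatnonzero(~done)
        if len(candidates) < config.batch_size:
            raise RoDatasetError("parameter space exhausted")
        if c == 0:
            batch = rng.choice(candidates, size=config.batch_size, replace=False)
        else:
            # stable top-k: ties fall back to row order (lexicographic keys)
            order = np.argsort(-acq[candidates], kind="stable")
            batch = candidates[order[: config.batch_size]]
        y = config.truth.sample(space.rows.iloc[batch], rng)
        measured[batch] = y
        cycle_of[batch] = c

    rows = space.rows.copy()
    mcol = column_name_for("yield", ColumnRole("measured_target"))
    ccol = column_name_for("cycle", ColumnRole("cycle_index"))
    rows[mcol] = measured
    rows[ccol] = cycle_of
    roles[mcol] = ColumnRole("measured_target")
    roles[ccol] = ColumnRole("cycle_index")
    for name, vals in new_cols.items():
        rows[name] = vals
    ds = CampaignDataset(list(config.params), rows, roles, n_cycles=config.n_cycles)
    ds.validate()
    return ds


def _add_cycle_columns(new_cols, roles, c, mean, sd, acq):
    for base, role_name, vals in (
        ("pred", "prediction_mean", mean),
        ("pred_std", "prediction_std", sd),
        ("acq", "acquisition", acq),
    ):
        role = ColumnRole(role_name, cycle=c)
        name = column_name_for(base, role)
        new_cols[name] = vals
        roles[name] = role


# ---------------------------------------------------------------------------
# Presets & convenience
# ---------------------------------------------------------------------------

#: Case-study-shaped spaces: a 3x3x4x22 = 792-experiment C-N coupling screen
#: and a 12x4x4x3x3 = 1728-experiment arylation screen with two numeric
#: variables (three temperatures, three concentrations).
PRESETS: dict[str, list[tuple[str, str, int]]] = {
    "buchwald792": [
        ("aryl_halide", CATEGORICAL, 3),
        ("base", CATEGORICAL, 3),
        ("ligand", CATEGORICAL, 4),
        ("additive", CATEGORICAL, 22),
    ],
    "arylation1728": [
        ("ligand", CATEGORICAL, 12),
        ("base", CATEGORICAL, 4),
        ("solvent", CATEGORICAL, 4),
        ("temperature", NUMERIC, 3),
        ("concentration", NUMERIC, 3),
    ],
}

_NUMERIC_LEVELS = {"temperature": (25.0, 60.0, 90.0), "concentration": (0.05, 0.1, 0.15)}


def preset_params(name: str) -> list[ParameterSpec]:
    """Parameter specs for a named campaign preset."""
    if name not in PRESETS:
        raise RoDatasetError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    out = []
    for pname, kind, n_levels in PRESETS[name]:
        if kind == NUMERIC:
            values = _NUMERIC_LEVELS.get(pname) or tuple(float(i) for i in range(n_levels))
            values = values[:n_levels]
        else:
            values = tuple(f"{pname}_{i:02d}" for i in range(n_levels))
        out.append(ParameterSpec(pname, kind, values))
    return out


def planted_truth(
    params: Sequence[ParameterSpec],
    seed: int,
    noise_sd: float = 2.0,
    dominant: tuple[str, object] | None = None,
    dominant_effect: float = 40.0,
    interaction: tuple[tuple[str, object], tuple[str, object]] | None = None,
    interaction_effect: float = 25.0,
    main_sd: float = 6.0,
) -> TruthModel:
    """Random truth surface with optional planted structure.

    Main effects are drawn Normal(0, main_sd) per level; a ``dominant``
    (parameter, level) gets a large positive effect, and an ``interaction``
    pair a positive synergy — the structures the analysis stack is meant to
    recover.  A planted critical combination also raises its constituent
    levels moderately (one third of the synergy each): in real campaigns
    the reagents of a winning combination tend to perform decently on their
    own, and a combination whose members look average individually would
    never surface in a main-effect-driven top set.
    """
    rng = np.random.default_rng(seed)
    main = {
        p.name: {v: float(rng.normal(0.0, main_sd)) for v in p.values} for p in params
    }
    if dominant is not None:
        pname, level = dominant
        main[pname][level] = dominant_effect
    interactions = {}
    if interaction is not None:
        interactions[frozenset(interaction)] = interaction_effect
        for pname, level in interaction:
            main[pname][level] = interaction_effect / 3.0
    return TruthModel(base=30.0, main_effects=main, interactions=interactions, noise_sd=noise_sd)


def simulate_campaign(
    preset: str = "buchwald792",
    n_cycles: int = 8,
    batch_size: int = 5,
    seed: int = 0,
    acquisition: str = "expected_improvement",
    noise_sd: float = 2.0,
    write_attributions: bool = True,
) -> CampaignDataset:
    """One-call campaign on a preset space with seeded planted structure.

    The dominant level and interaction pair are chosen deterministically
    from the seed, so a fixed seed yields a bitwise-identical campaign.
    """
    params = preset_params(preset)
    rng = np.random.default_rng(seed + 1_000_003)
    p_dom = params[int(rng.integers(len(params)))]
    dominant = (p_dom.name, p_dom.values[int(rng.integers(len(p_dom.values)))])
    others = [p for p in params if p.name != p_dom.name]
    p_a, p_b = (others + [p_dom])[:2] if len(others) >= 2 else (params[0], params[-1])
    interaction = (
        (p_a.name, p_a.values[int(rng.integers(len(p_a.values)))]),
        (p_b.name, p_b.values[int(rng.integers(len(p_b.values)))]),
    )
    truth = planted_truth(
        params, seed=seed, noise_sd=noise_sd, dominant=dominant, interaction=interaction
    )
    config = CampaignConfig(
        params=tuple(params),
        truth=truth,
        n_cycles=n_cycles,
        batch_size=batch_size,
        acquisition=acquisition,
        seed=seed,
        write_attributions=write_attributions,
    )
    return run_campaign(config)
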