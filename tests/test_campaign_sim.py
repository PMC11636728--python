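"""Surrogate model, acquisition functions, and the simulated campaign loop."""

import numpy as np
import pytest
from scipy.stats import norm

import rospace as rs
from rospace.ro_dataset import RoDatasetError


def _cat(name, n):
    return rs.ParameterSpec(name, "categorical", tuple(f"{name}{i}" for i in range(n)))


@pytest.fixture(scope="module")
def cube_params():
    return [_cat("lig", 5), _cat("base", 5), _cat("solv", 5)]


@pytest.fixture(scope="module")
def cube_fm(cube_params):
    space = rs.build_parameter_space(cube_params)
    return space, rs.encode_features(space)


class TestSurrogate:
    def test_no_data_returns_prior(self, cube_fm):
        _, fm = cube_fm
        model = rs.SurrogateModel(fm, prior_mean=30.0, prior_sd=25.0)
        mean, sd = rs.surrogate_predict(model, 17)
        assert (mean, sd) == (30.0, 25.0)

    def test_training_point_is_interpolated(self, cube_fm):
        _, fm = cube_fm
        model = rs.SurrogateModel(fm, floor_sd=1.0)
        model.fit([10], [77.7])
        mean, sd = rs.surrogate_predict(model, 10)
        assert mean == pytest.approx(77.7, abs=1e-6)
        assert sd <= model.floor_sd + 1e-6

    def test_far_query_reverts_to_prior(self, cube_params):
        # query at Gower distance 1 from every training point, tiny bandwidth
        space = rs.build_parameter_space(cube_params)
        fm = rs.encode_features(space)
        model = rs.SurrogateModel(fm, bandwidth=0.05, prior_mean=30.0, prior_sd=25.0)
        keys = list(space.row_keys())
        train = keys.index(("lig0", "base0", "solv0"))
        query = keys.index(("lig1", "base1", "solv1"))  # all three levels differ
        model.fit([train], [90.0])
        mean, sd = rs.surrogate_predict(model, query)
        assert mean == pytest.approx(30.0, abs=1e-6)
        assert sd == pytest.approx(25.0 + model.floor_sd, abs=1e-6)

    def test_uncertainty_lower_near_data(self, cube_fm):
        _, fm = cube_fm
        model = rs.SurrogateModel(fm)
        model.fit([0], [50.0])
        # row 1 differs in one of three parameters; row 124 in all three
        _, sd_near = rs.surrogate_predict(model, 1)
        _, sd_far = rs.surrogate_predict(model, 124)
        assert sd_near < sd_far

    def test_invalid_bandwidth_rejected(self, cube_fm):
        _, fm = cube_fm
        with pytest.raises(RoDatasetError):
            rs.SurrogateModel(fm, bandwidth=0.0)


class TestExpectedImprovement:
    def test_degenerate_sd_zero(self):
        assert rs.expected_improvement(40.0, 0.0, 50.0) == 0.0
        assert rs.expected_improvement(55.0, 0.0, 50.0) == 5.0

    def test_at_the_incumbent_ei_is_sd_times_phi0(self):
        # z = 0: EI = sd * pdf(0) = sd * 0.3989...
        for s in (1.0, 2.5, 10.0):
            assert rs.expected_improvement(50.0, s, 50.0) == pytest.approx(
                s * norm.pdf(0.0), rel=1e-12
            )

    def test_unit_case_closed_form(self):
        # mean - best = 1, sd = 1: EI = Phi(1) + pdf(1) = 1.08332...
        expected = norm.cdf(1.0) + norm.pdf(1.0)
        assert rs.expected_improvement(51.0, 1.0, 50.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.08332, abs=5e-6)

    def test_always_nonnegative_and_vectorized(self, rng):
        mean = rng.normal(50, 20, size=100)
        sd = rng.uniform(0, 10, size=100)
        ei = rs.expected_improvement(mean, sd, 60.0)
        assert ei.shape == (100,)
        assert np.all(ei >= 0)


class TestOcclusionAttribution:
    def test_constant_surrogate_gives_zero(self, cube_fm):
        space, fm = cube_fm
        model = rs.SurrogateModel(fm, prior_mean=30.0)
        model.fit([0, 1], [30.0, 30.0])  # constant measurements = prior
        for p in ("lig", "base", "solv"):
            assert rs.occlusion_attribution(model, space, 60, p) == pytest.approx(0.0, abs=1e-9)

    def test_irrelevant_parameters_get_zero_attribution(self):
        # the surrogate depends on lig only (base/solv have zero distance
        # weight), so occluding the inert parameters moves nothing
        params = [
            rs.ParameterSpec("lig", "categorical", tuple(f"lig{i}" for i in range(5))),
            rs.ParameterSpec("base", "categorical", tuple(f"base{i}" for i in range(5)), weight=0.0),
            rs.ParameterSpec("solv", "categorical", tuple(f"solv{i}" for i in range(5)), weight=0.0),
        ]
        space = rs.build_parameter_space(params)
        fm = rs.encode_features(space)
        keys = list(space.row_keys())
        train_idx = [keys.index((f"lig{i}", "base0", "solv0")) for i in range(5)]
        model = rs.SurrogateModel(fm)
        model.fit(train_idx, [10.0 * i for i in range(5)])
        query = keys.index(("lig4", "base3", "solv2"))
        assert rs.occlusion_attribution(model, space, query, "base") == pytest.approx(0.0, abs=1e-9)
        assert rs.occlusion_attribution(model, space, query, "solv") == pytest.approx(0.0, abs=1e-9)
        assert rs.occlusion_attribution(model, space, query, "lig") > 1.0

    def test_dominant_level_attribution_largest(self, cube_params):
        # planted dominant lig level: once the campaign has measured enough
        # of its rows for the model to generalize the ligand effect, the lig
        # attribution dominates the other parameters for experiments
        # containing that level
        hits = 0
        runs = 20
        for seed in range(runs):
            truth = rs.planted_truth(
                cube_params, seed=seed, noise_sd=0.0, dominant=("lig", "lig2")
            )
            ds = rs.run_campaign(
                rs.CampaignConfig(
                    params=tuple(cube_params),
                    truth=truth,
                    n_cycles=4,
                    batch_size=5,
                    acquisition="greedy_mean",
                    seed=seed,
                )
            )
            last = ds.n_cycles - 1
            mask = ((ds.rows["lig"] == "lig2") & ds.rows[ds.measured_column].notna()).to_numpy()
            idx = np.flatnonzero(mask)
            wins = 0
            for i in idx:
                attrs = {
                    p.name: abs(
                        ds.rows[
                            ds.columns_with_role(
                                "attribution", cycle=last, parameter_link=p.name
                            )[0]
                        ].iloc[i]
                    )
                    for p in cube_params
                }
                wins += max(attrs, key=attrs.get) == "lig"
            if len(idx) and wins > len(idx) / 2:
                hits += 1
        assert hits >= 0.9 * runs


class TestRunCampaign:
    def test_single_cycle_measures_one_random_batch(self, cube_params):
        truth = rs.planted_truth(cube_params, seed=3)
        ds = rs.run_campaign(
            rs.CampaignConfig(params=tuple(cube_params), truth=truth, n_cycles=1, seed=5)
        )
        measured = ds.rows[ds.measured_column].notna()
        assert int(measured.sum()) == 5
        assert set(ds.rows.loc[measured, ds.cycle_column]) == {0.0}

    def test_output_parses_and_validates(self, small_campaign, tmp_path):
        path = tmp_path / "c.csv"
        rs.write_dataset(small_campaign, path)
        back = rs.parse_dataset(path)
        back.validate()
        # every per-cycle family complete
        for fam in ("prediction_mean", "prediction_std", "acquisition"):
            for c in range(back.n_cycles):
                assert back.columns_with_role(fam, cycle=c)

    def test_batches_exact_and_never_reselected(self, cube_params):
        truth = rs.planted_truth(cube_params, seed=9, noise_sd=1.0)
        ds = rs.run_campaign(
            rs.CampaignConfig(params=tuple(cube_params), truth=truth, n_cycles=4, seed=1)
        )
        cycles = ds.rows[ds.cycle_column].dropna()
        counts = cycles.value_counts()
        assert all(counts[c] == 5 for c in range(4))

    def test_max_uncertainty_batches_are_above_average_sd(self, cube_params):
        truth = rs.planted_truth(cube_params, seed=2, noise_sd=1.0)
        ds = rs.run_campaign(
            rs.CampaignConfig(
                params=tuple(cube_params),
                truth=truth,
                n_cycles=3,
                acquisition="max_uncertainty",
                seed=4,
                write_attributions=False,
            )
        )
        for c in range(1, ds.n_cycles):
            sd_col = ds.columns_with_role("prediction_std", cycle=c)[0]
            sds = ds.rows[sd_col].to_numpy(float)
            batch = ds.rows[ds.cycle_column] == c
            assert sds[batch.to_numpy()].mean() >= sds.mean()

    def test_bitwise_reproducible(self, cube_params):
        truth = rs.planted_truth(cube_params, seed=7, noise_sd=2.0)
        cfg = rs.CampaignConfig(params=tuple(cube_params), truth=truth, n_cycles=2, seed=13)
        a = rs.run_campaign(cfg)
        b = rs.run_campaign(cfg)
        import pandas.testing as pdt

        pdt.assert_frame_equal(a.rows, b.rows)

    def test_oversized_campaign_rejected(self, cube_params):
        truth = rs.planted_truth(cube_params, seed=0)
        with pytest.raises(RoDatasetError):
            rs.CampaignConfig(params=tuple(cube_params), truth=truth, n_cycles=50, batch_size=5)

    def test_measured_sd_nonincreasing_over_cycles(self, small_campaign):
        std = rs.temporal_matrix(small_campaign, "prediction_std").values
        cyc = small_campaign.rows[small_campaign.cycle_column].to_numpy(float)
        for i, c in enumerate(cyc):
            if np.isnan(c):
                continue
            tail = std[i, int(c) + 1 :]
            assert np.all(np.diff(tail) <= 1e-9)


class TestGreedyRecovery:
    def test_dominant_level_found_within_three_cycles(self, cube_params):
        # noise-free greedy campaigns on the 125-point space: the planted
        # dominant ligand level is measured within 3 cycles in nearly every
        # run (the optimistic neutral prior makes greedy explore unseen
        # regions until something beats it)
        found = 0
        runs = 30
        space = rs.build_parameter_space(cube_params)
        for seed in range(runs):
            truth = rs.planted_truth(
                cube_params, seed=1000 + seed, noise_sd=0.0, dominant=("lig", "lig3")
            )
            ds = rs.run_campaign(
                rs.CampaignConfig(
                    params=tuple(cube_params),
                    truth=truth,
                    n_cycles=3,
                    batch_size=5,
                    acquisition="greedy_mean",
                    seed=seed,
                    write_attributions=False,
                )
            )
            measured = ds.rows[ds.measured_column].notna()
            if (ds.rows.loc[measured, "lig"] == "lig3").any():
                found += 1
        assert found >= 0.95 * runs

    def test_interaction_recovered_by_group_difference(self, cube_params):
        # planted (lig, solv) critical combination: splitting top-decile
        # truth yields vs rest puts both interacting levels among the top-3
        # |delta| entries, provided the synergy dominates the background
        # main-effect variation
        space = rs.build_parameter_space(cube_params)
        keys = list(space.row_keys())
        hits = 0
        runs = 30
        for seed in range(runs):
            truth = rs.planted_truth(
                cube_params,
                seed=seed,
                noise_sd=0.0,
                interaction=(("lig", "lig1"), ("solv", "solv4")),
                interaction_effect=25.0,
                main_sd=3.0,
            )
            y = truth.latent(space.rows)
            cutoff = np.quantile(y, 0.9)
            top = [k for k, yy in zip(keys, y) if yy >= cutoff]
            rest = [k for k, yy in zip(keys, y) if yy < cutoff]
            gd = rs.group_difference(space, top, rest, threshold=0.0)
            top3 = {(p, l) for p, l, _ in sorted(gd.entries, key=lambda e: -abs(e[2]))[:3]}
            if ("lig", "lig1") in top3 and ("solv", "solv4") in top3:
                hits += 1
        assert hits >= 0.85 * runs
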