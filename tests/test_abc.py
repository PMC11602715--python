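"""ABC machinery: priors, MAD-standardised rejection, regression adjustment,
posterior-predictive checks and phylogenetic-age inference."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonefate.abc_inference import (
    PriorSpec,
    abc_regress,
    abc_reject,
    phyloage_abc,
    posterior_predictive_check,
    run_phyloage_reference,
    run_reference_table,
    sample_prior,
)
from clonefate.simulator import SimulationParams


class TestPrior:
    def test_bounds_match_printed_range(self):
        spec = PriorSpec()
        draws = sample_prior(spec, 5000, seed=0)
        assert draws["n_trans"].min() >= round(10 ** 2.7)   # 501
        assert draws["n_trans"].max() <= round(10 ** 4.7)   # 50119
        assert 10 ** 2.7 == pytest.approx(501.19, abs=0.01)
        assert 10 ** 4.7 == pytest.approx(50118.7, abs=0.1)

    def test_log10_uniformity(self):
        # a pool above the n_trans range keeps the marginal untruncated
        draws = sample_prior(PriorSpec(n_hsc_fixed=100_000), 10_000, seed=1)
        u = (draws["log10_ntrans"] - 2.7) / 2.0
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_determinism(self):
        a = sample_prior(PriorSpec(), 50, seed=3)
        b = sample_prior(PriorSpec(), 50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_incompatible_pool_rejected(self):
        spec = PriorSpec(log10_ntrans=(3.2, 4.7), n_hsc_fixed=1000)  # 10^3.2 > 1000
        with pytest.raises(ValueError, match="pool size"):
            sample_prior(spec, 200, seed=0)

    def test_joint_prior_truncated_to_feasible(self):
        draws = sample_prior(PriorSpec(), 5000, seed=4)
        assert (draws["n_trans"] <= draws["n_hsc"]).all()

    def test_prior_sample_table(self):
        table = pd.DataFrame({"n_hsc": [60_000, 80_000],
                              "driver_rate": [1.0, 2.0],
                              "gamma_shape": [0.5, 0.5],
                              "gamma_rate": [25.0, 30.0]})
        draws = sample_prior(PriorSpec(prior_sample=table), 100, seed=2)
        assert set(draws["n_hsc"]) <= {60_000, 80_000}


def _toy_reference(n=120, seed=0):
    rng = np.random.default_rng(seed)
    params = pd.DataFrame({"theta": rng.uniform(0, 10, n)})
    stats_ = pd.DataFrame({
        "s1": params["theta"] + rng.normal(0, 0.1, n),
        "s2": rng.normal(5, 2, n),
    })
    return params, stats_


class TestRejection:
    def test_exact_match_accepted_at_distance_zero(self):
        params, stats_ = _toy_reference()
        obs = stats_.iloc[17]
        res = abc_reject(obs, stats_, params, quantile=0.05)
        assert res.distances.min() == pytest.approx(0.0, abs=1e-12)
        assert params.iloc[17]["theta"] in res.accepted_params["theta"].values

    def test_quantile_one_accepts_all(self):
        params, stats_ = _toy_reference()
        res = abc_reject(stats_.iloc[0], stats_, params, quantile=1.0)
        assert len(res.accepted_params) == len(params)

    def test_mad_euclidean_hand_arithmetic(self):
        # 120 rows engineered so the MAD scaling and every distance can be
        # computed by hand: rows 0-39 = (0,0), 40-59 = (1,0), 60-79 = (1,4),
        # 80-119 = (2,4); observed (1,0).
        base = pd.DataFrame({"s1": [0.0] * 40 + [1.0] * 40 + [2.0] * 40,
                             "s2": [0.0] * 60 + [4.0] * 60})
        params = pd.DataFrame({"theta": np.arange(120, dtype=float)})
        obs = pd.Series({"s1": 1.0, "s2": 0.0})
        res = abc_reject(obs, base, params, quantile=0.25)
        # s1: median 1, abs devs {1,0,1} -> MAD = 1.4826; s2: median 2 (even
        # split of 0s and 4s), abs devs all 2 -> MAD = 2 * 1.4826
        assert res.scale["s1"] == pytest.approx(1.4826)
        assert res.scale["s2"] == pytest.approx(2 * 1.4826)
        # the 30 accepted = 20 exact matches (rows 40-59, d = 0) plus 10 of
        # the (0,0) rows at d = 1/1.4826
        assert len(res.accepted_params) == 30
        accepted = set(res.accepted_params["theta"].astype(int))
        assert set(range(40, 60)) <= accepted
        assert res.distances.max() == pytest.approx(1 / 1.4826)

    def test_accepted_distances_below_rejected(self):
        params, stats_ = _toy_reference()
        obs = pd.Series({"s1": 5.0, "s2": 5.0})
        res = abc_reject(obs, stats_, params, quantile=0.1)
        X = stats_.to_numpy(dtype=float)
        med = np.median(X, axis=0)
        mad = 1.4826 * np.median(np.abs(X - med), axis=0)
        d_all = np.sqrt((((X - obs.to_numpy()) / mad) ** 2).sum(axis=1))
        assert res.distances.max() <= np.partition(d_all, len(res.distances))[
            len(res.distances)] + 1e-12

    def test_affine_invariance(self):
        params, stats_ = _toy_reference()
        obs = pd.Series({"s1": 5.0, "s2": 5.0})
        res1 = abc_reject(obs, stats_, params, quantile=0.1)
        scaled = stats_.copy()
        scaled["s1"] = scaled["s1"] * 7.0 + 3.0
        obs2 = pd.Series({"s1": 5.0 * 7.0 + 3.0, "s2": 5.0})
        res2 = abc_reject(obs2, scaled, params, quantile=0.1)
        assert sorted(res1.accepted_params["theta"]) == pytest.approx(
            sorted(res2.accepted_params["theta"]))

    def test_zero_mad_statistic_dropped(self):
        params, stats_ = _toy_reference()
        stats_ = stats_.assign(s3=1.0)
        obs = pd.Series({"s1": 5.0, "s2": 5.0, "s3": 1.0})
        with pytest.warns(UserWarning, match="zero MAD"):
            res = abc_reject(obs, stats_, params, quantile=0.1)
        assert "s3" not in res.used_stats

    def test_small_table_rejected(self):
        params, stats_ = _toy_reference(n=50)
        with pytest.raises(ValueError, match="100"):
            abc_reject(stats_.iloc[0], stats_, params, quantile=0.1)


class TestRegression:
    def test_rejection_is_noop(self):
        params, stats_ = _toy_reference()
        res = abc_reject(stats_.iloc[3], stats_, params, quantile=0.2)
        assert abc_regress(res, "rejection") is res

    def test_noise_parameters_barely_adjusted(self):
        rng = np.random.default_rng(0)
        n = 400
        params = pd.DataFrame({"theta": rng.normal(0, 1, n)})  # independent
        stats_ = pd.DataFrame({"s1": rng.normal(0, 1, n), "s2": rng.normal(0, 1, n)})
        obs = pd.Series({"s1": 0.0, "s2": 0.0})
        res = abc_reject(obs, stats_, params, quantile=0.25)
        adj = abc_regress(res, "loclinear")
        mc_se = res.accepted_params["theta"].std() / np.sqrt(len(res.accepted_params))
        shift = abs(adj.accepted_params["theta"].median()
                    - res.accepted_params["theta"].median())
        assert shift < 3 * mc_se

    @pytest.mark.parametrize("method", ["loclinear", "ridge"])
    def test_linear_map_concentrates(self, method):
        rng = np.random.default_rng(1)
        n = 500
        theta = rng.uniform(0, 10, n)
        params = pd.DataFrame({"theta": theta})
        stats_ = pd.DataFrame({"s1": 2.0 * theta + rng.normal(0, 0.05, n),
                               "s2": rng.normal(0, 1, n)})
        obs = pd.Series({"s1": 2.0 * 5.0, "s2": 0.0})
        res = abc_reject(obs, stats_, params, quantile=0.2)
        adj = abc_regress(res, method)
        assert adj.accepted_params["theta"].var() < res.accepted_params["theta"].var() / 5
        assert adj.accepted_params["theta"].median() == pytest.approx(5.0, abs=0.2)

    def test_neuralnet_runs(self):
        params, stats_ = _toy_reference(n=200)
        obs = pd.Series({"s1": 5.0, "s2": 5.0})
        res = abc_reject(obs, stats_, params, quantile=0.3)
        adj = abc_regress(res, "neuralnet", seed=0)
        assert adj.method == "neuralnet"
        assert np.isfinite(adj.accepted_params["theta"]).all()


class TestPosteriorPredictive:
    def test_centroid_and_far_limits(self):
        params, stats_ = _toy_reference(n=300)
        obs = pd.Series({"s1": 5.0, "s2": 5.0})
        res = abc_reject(obs, stats_, params, quantile=0.3)
        centroid = res.accepted_stats[res.used_stats].mean()
        assert posterior_predictive_check(res, centroid) > 0.9
        far = pd.Series({"s1": 1e4, "s2": -1e4})
        assert posterior_predictive_check(res, far) == 0.0


class TestReferenceTable:
    def test_shape_and_determinism(self):
        pair = SimulationParams(n_hsc=500, n_trans=100, donor_age_hct=20,
                                donor_age_bd=28, n_colonies_donor=25,
                                n_colonies_recipient=25)
        spec = PriorSpec(log10_ntrans=(1.5, 2.5), n_hsc_fixed=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref1 = run_reference_table(spec, pair, 10, seed=5)
            ref2 = run_reference_table(spec, pair, 10, seed=5)
        assert ref1.stats["original"].shape == (10, 13)
        pd.testing.assert_frame_equal(ref1.params, ref2.params)
        pd.testing.assert_frame_equal(ref1.stats["original"], ref2.stats["original"])


class TestPhyloAge:
    @pytest.fixture(scope="class")
    def reference(self):
        base = SimulationParams(n_hsc=800, n_trans=200, n_colonies_donor=50,
                                n_colonies_recipient=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_phyloage_reference(base, 150, age_range=(20, 100),
                                          n_colonies=50, seed=9)

    def test_age_monotonicity(self, reference):
        ref_params, ref_stats = reference
        young = ref_stats[ref_params["age"] < 40].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_y = phyloage_abc(young, ref_params, ref_stats, quantile=0.1)
            old = ref_stats[ref_params["age"] > 75].mean()
            res_o = phyloage_abc(old, ref_params, ref_stats, quantile=0.1)
        assert res_y.posterior_summary("age")["median"] < \
            res_o.posterior_summary("age")["median"]

    def test_quantile_one_returns_prior(self, reference):
        ref_params, ref_stats = reference
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = phyloage_abc(ref_stats.iloc[0], ref_params, ref_stats,
                               quantile=1.0)
        assert len(res.accepted_params) == len(ref_params)

    def test_tree_size_guard(self, reference):
        ref_params, ref_stats = reference
        with pytest.raises(ValueError, match="outside reference range"):
            phyloage_abc(ref_stats.iloc[0], ref_params, ref_stats,
                         n_colonies=500)
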