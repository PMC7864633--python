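import warnings

import numpy as np
import pandas as pd
import pytest

from stripeburst.simulate import SimulationConfig, simulate_embryo_dataset
from stripeburst.stripes import (
    StripeModel,
    analyze_movie_stripes,
    assign_nuclei_to_stripes,
    bootstrap_registration,
    cluster_time_windows,
    fit_stripe_orientation,
    fit_stripe_position_model,
    map_to_ap_and_reorient,
    register_stripes_across_movies,
)


def two_stripe_points(n=200, seed=0, centers=(100.0, 200.0), sd=5.0, t0=1500.0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, cx in enumerate(centers):
        for i in range(n):
            rows.append(
                {
                    "movie_id": "m01",
                    "nucleus_id": f"s{label}_{i}",
                    "t_s": t0 + 20.0 * rng.integers(0, 60),
                    "x_px": rng.normal(cx, sd),
                    "y_px": rng.uniform(0, 256),
                    "fluo_au": 100.0,
                    "truth": label,
                }
            )
    return pd.DataFrame(rows)


class TestClustering:
    def test_single_stripe_all_labeled(self):
        df = two_stripe_points(centers=(150.0,))
        out = cluster_time_windows(df, 1, seed=0)
        assert (out["stripe_local"] == 0).all()

    def test_well_separated_stripes_recovered(self):
        df = two_stripe_points()
        out = cluster_time_windows(df, 2, seed=0)
        acc = (out["stripe_local"] == out["truth"]).mean()
        assert acc >= 0.99

    def test_seed_determinism(self):
        df = two_stripe_points()
        a = cluster_time_windows(df, 2, seed=3)["stripe_local"]
        b = cluster_time_windows(df, 2, seed=3)["stripe_local"]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_no_active_points_rejected(self):
        df = two_stripe_points()
        df["fluo_au"] = 0.0
        with pytest.raises(ValueError):
            cluster_time_windows(df, 2)


class TestOrientation:
    def test_vertical_stripe_slope_zero(self):
        y = np.r_[np.full(10, 50.0), np.full(10, 200.0)]
        x = np.full(20, 80.0)
        assert fit_stripe_orientation(x, y) == 0.0

    def test_hand_medians(self):
        # bottom median (50, 64), top median (60, 192) -> slope 10/128
        x = np.array([50.0, 60.0])
        y = np.array([64.0, 192.0])
        assert fit_stripe_orientation(x, y) == pytest.approx(10 / 128)

    def test_mirror_negates_slope(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 256, 100)
        x = 100 + 0.2 * (y - 128) + rng.normal(0, 1, 100)
        s1 = fit_stripe_orientation(x, y)
        s2 = fit_stripe_orientation(-x, y)
        assert s2 == pytest.approx(-s1)

    def test_empty_half_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert fit_stripe_orientation([1.0, 2.0], [10.0, 20.0]) == 0.0


class TestPositionModel:
    def _points(self, xfun, n=300, seed=0, slope=0.0):
        rng = np.random.default_rng(seed)
        t = rng.uniform(1500, 3000, n)
        y = rng.uniform(0, 256, n)
        x = xfun(t) + slope * (y - 128)
        return pd.DataFrame({"t_s": t, "x_px": x, "y_px": y})

    def test_stationary_stripe_zero_velocity(self):
        m = fit_stripe_position_model(self._points(lambda t: 500.0), 0.0, "m01", 2)
        assert m.c1_px_per_s == pytest.approx(0.0, abs=1e-9)
        assert m.c0_px == pytest.approx(500.0)

    def test_linear_motion_recovered(self):
        m = fit_stripe_position_model(self._points(lambda t: 500.0 - 2.0 * t), 0.0, "m01", 2)
        assert m.c1_px_per_s == pytest.approx(-2.0, rel=1e-9)
        assert m.c0_px == pytest.approx(500.0, rel=1e-6)

    def test_translation_equivariance(self):
        pts = self._points(lambda t: 400.0 - 0.5 * t)
        m1 = fit_stripe_position_model(pts, 0.0, "m01", 2)
        pts2 = pts.assign(x_px=pts.x_px + 37.0)
        m2 = fit_stripe_position_model(pts2, 0.0, "m01", 2)
        assert m2.c0_px - m1.c0_px == pytest.approx(37.0, abs=1e-9)
        assert m2.c1_px_per_s == pytest.approx(m1.c1_px_per_s, abs=1e-12)


class TestApMapping:
    def test_zero_slope_identity(self):
        df = pd.DataFrame({"x_px": [250.0], "y_px": [30.0], "stripe": [1]})
        models = {1: StripeModel("m01", 1, 0.0, 250.0, 0.0)}
        ap = map_to_ap_and_reorient(df, models, "stripe", 0.0, 1000.0)
        assert ap[0] == pytest.approx(0.25)

    def test_equal_poles_rejected(self):
        df = pd.DataFrame({"x_px": [250.0], "y_px": [30.0], "stripe": [1]})
        with pytest.raises(ValueError):
            map_to_ap_and_reorient(df, {}, "stripe", 5.0, 5.0)

    def test_detilting_reduces_within_stripe_spread(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 256, 400)
        x = 300 + 0.4 * (y - 128) + rng.normal(0, 3, 400)
        df = pd.DataFrame({"x_px": x, "y_px": y, "stripe": 1})
        models = {1: StripeModel("m01", 1, 0.4, 300.0, 0.0)}
        ap_corr = map_to_ap_and_reorient(df, models, "stripe", 0.0, 1000.0)
        ap_raw = (x - 0.0) / 1000.0
        assert ap_corr.std() < ap_raw.std()


class TestAssignment:
    def _models(self):
        return {
            2: StripeModel("m01", 2, 0.0, 200.0, 0.0),
            3: StripeModel("m01", 3, 0.0, 400.0, 0.0),
        }

    def _df(self, xs, nucleus="n0001"):
        n = len(xs)
        return pd.DataFrame(
            {
                "movie_id": "m01",
                "nucleus_id": nucleus,
                "frame": np.arange(n),
                "t_s": 1500.0 + 20.0 * np.arange(n),
                "x_px": xs,
                "y_px": 128.0,
            }
        )

    def test_always_nearest_is_consensus(self):
        out = assign_nuclei_to_stripes(self._df([210.0] * 5), self._models())
        assert (out["consensus_stripe"] == 2).all()

    def test_majority_vote(self):
        xs = [210.0] * 6 + [390.0] * 4  # 60% stripe 2, 40% stripe 3
        out = assign_nuclei_to_stripes(self._df(xs), self._models())
        assert out["consensus_stripe"].iloc[0] == 2

    def test_equidistant_tie_goes_anterior(self):
        out = assign_nuclei_to_stripes(self._df([300.0] * 4), self._models())
        assert (out["stripe"] == 2).all()

    def test_positions_frozen_before_25_min(self):
        models = {
            2: StripeModel("m01", 2, 0.0, 200.0, -0.1),  # moving stripe
            3: StripeModel("m01", 3, 0.0, 400.0, 0.0),
        }
        df = self._df([190.0])
        df["t_s"] = 600.0  # 10 min; stripe-2 position must be taken at 25 min
        out = assign_nuclei_to_stripes(df, models)
        # at 25 min stripe 2 sits at 200 - 0.1*1500 = 50 -> nucleus closer to it?
        # |190-50|=140 vs |190-400|=210 -> stripe 2
        assert out["stripe"].iloc[0] == 2


class TestRegistration:
    def _setup(self, ap_anchors):
        models_by_movie, poles = {}, {}
        for i, ap in enumerate(ap_anchors):
            mid = f"m{i + 1:02d}"
            # poles at 0 and 1000 px: AP == x/1000
            models_by_movie[mid] = {2: StripeModel(mid, 2, 0.0, ap * 1000.0, 0.0)}
            poles[mid] = (0.0, 1000.0)
        return models_by_movie, poles

    def test_single_movie_zero_offsets(self):
        models, poles = self._setup([0.40])
        table = register_stripes_across_movies(models, poles)
        assert (table["registration_offset_ap"] == 0.0).all()

    def test_two_movies_hand_offsets(self):
        models, poles = self._setup([0.40, 0.42])
        table = register_stripes_across_movies(models, poles)
        offs = dict(zip(table["movie_id"], table["registration_offset_ap"]))
        assert offs["m01"] == pytest.approx(+0.01)
        assert offs["m02"] == pytest.approx(-0.01)
        registered = table["ap_at_anchor"] + table["registration_offset_ap"]
        np.testing.assert_allclose(registered, 0.41, atol=1e-12)

    def test_registration_exact_at_anchor(self):
        models, poles = self._setup([0.38, 0.405, 0.43])
        table = register_stripes_across_movies(models, poles)
        registered = table["ap_at_anchor"] + table["registration_offset_ap"]
        assert np.ptp(registered.to_numpy()) < 1e-12

    def test_bootstrap_sd_small_for_consistent_movies(self):
        models, poles = self._setup([0.400, 0.401, 0.399, 0.4005])
        boot = bootstrap_registration(models, poles, n_boot=50, seed=0)
        assert boot["pooled_sd_ap"] < 0.002  # well under one stripe width


class TestEndToEnd:
    def test_ground_truth_stripe_recovery_on_clean_embryo(self):
        # well-separated stripes (>= 4 sd gaps), no baseline activity, no
        # treadmilling: assignment must recover >= 98% of core nuclei
        sim = SimulationConfig(
            n_movies=1, stripes_per_movie=3, n_nuclei_per_movie=150,
            duration_min=40.0, seed=9, kon_baseline=0.0, r_baseline=0.0,
            never_on_interstripe_frac=1.0, drift_ap_pct_per_min=0.0,
        )
        ds = simulate_embryo_dataset(sim)
        meta = ds.movies["m01"]
        dfm = ds.traces[ds.traces.movie_id == "m01"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = analyze_movie_stripes(
                dfm, meta["stripe_ids"], activity_threshold_au=2 * sim.noise_sd_au, seed=1
            )
        asg = assign_nuclei_to_stripes(dfm, models)
        merged = asg.merge(
            ds.truth[["nucleus_id", "frame", "stripe_true"]], on=["nucleus_id", "frame"]
        )
        nuc = merged.groupby("nucleus_id").agg(
            cs=("consensus_stripe", "first"), st=("stripe_true", "first")
        )
        core = nuc[nuc.st > 0]
        assert (core.cs == core.st).mean() >= 0.98

    def test_assignment_invariant_under_movie_bootstrap(self, small_embryo):
        # registration offsets shift AP but never the stripe labels
        ds = small_embryo
        mid = "m01"
        meta = ds.movies[mid]
        dfm = ds.traces[ds.traces.movie_id == mid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = analyze_movie_stripes(
                dfm, meta["stripe_ids"], activity_threshold_au=30.0, seed=2
            )
        before = assign_nuclei_to_stripes(dfm, models)["consensus_stripe"].copy()
        for m in models.values():
            m.registration_offset_ap += 0.05  # any registration outcome
        after = assign_nuclei_to_stripes(dfm, models)["consensus_stripe"]
        np.testing.assert_array_equal(before.to_numpy(), after.to_numpy())
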