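"""Latin-hypercube design, RMSE objective, K-fold machinery and the
end-to-end truth-recovery behaviour of the biome calibration."""

import numpy as np
import pandas as pd
import pytest

import soildoc as sd
from soildoc import calibration, column, synthetic
from soildoc.calibration import (
    CalibrationBounds,
    ObservationSet,
    kfold_partition,
    latin_hypercube_sample,
    match_observations,
    rmse,
    select_best,
)
from soildoc.errors import InvalidInputError


class TestLatinHypercube:
    def test_each_dimension_occupies_all_strata(self):
        bounds = CalibrationBounds(kp=(1.0, 2.0), kdoc=(500.0, 1000.0))
        pairs = latin_hypercube_sample(bounds, 25, seed=3)
        assert pairs.shape == (25, 2)
        for d, (lo, hi) in enumerate([(1.0, 2.0), (500.0, 1000.0)]):
            strata = np.floor((pairs[:, d] - lo) / (hi - lo) * 25).astype(int)
            assert len(set(strata.tolist())) == 25
        assert np.all(pairs[:, 0] >= 1.0) and np.all(pairs[:, 0] <= 2.0)

    def test_seed_reproducibility(self):
        bounds = CalibrationBounds()
        a = latin_hypercube_sample(bounds, 10, seed=7)
        b = latin_hypercube_sample(bounds, 10, seed=7)
        np.testing.assert_array_equal(a, b)
        c = latin_hypercube_sample(bounds, 10, seed=8)
        assert not np.array_equal(a, c)

    def test_degenerate_bounds_pin_coordinate(self):
        bounds = CalibrationBounds(kp=(1.5, 1.5), kdoc=(500.0, 1000.0))
        with pytest.warns(UserWarning, match="degenerate"):
            pairs = latin_hypercube_sample(bounds, 5, seed=0)
        assert np.all(pairs[:, 0] == 1.5)

    def test_biome_bounds_from_table(self):
        b = CalibrationBounds.for_biome("boreal")
        assert b.kp == (1.0, 2.0)
        assert b.kdoc == (820.0, 4545.0)


class TestRmse:
    def test_identical_series(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_constant_offset(self):
        assert rmse([5.0, 6.0], [2.0, 3.0]) == pytest.approx(3.0)

    def test_empty_pairing_rejected(self):
        with pytest.raises(InvalidInputError):
            rmse([], [])


class TestKfold:
    def test_folds_are_disjoint_and_cover(self):
        sites = [f"s{i}" for i in range(10)]
        assignment = kfold_partition(sites, 5, seed=1)
        assert set(assignment) == set(sites)
        sizes = pd.Series(assignment).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_leave_one_out(self):
        sites = ["a", "b", "c"]
        assignment = kfold_partition(sites, 3, seed=0)
        assert sorted(assignment.values()) == [0, 1, 2]

    def test_seed_reproducibility(self):
        sites = [f"s{i}" for i in range(9)]
        assert kfold_partition(sites, 3, 5) == kfold_partition(sites, 3, 5)

    @pytest.mark.parametrize("k", [1, 11])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(InvalidInputError):
            kfold_partition([f"s{i}" for i in range(10)], k)


class TestSelection:
    def test_lowest_rmse_wins(self):
        pairs = np.array([[1.0, 600.0], [1.5, 700.0], [2.0, 800.0]])
        assert select_best(pairs, np.array([3.0, 1.0, 2.0])) == 1

    def test_tie_breaks_to_smaller_kp_then_kdoc(self):
        pairs = np.array([[1.5, 700.0], [1.2, 900.0], [1.2, 650.0]])
        assert select_best(pairs, np.array([1.0, 1.0, 1.0])) == 2
        pairs2 = np.array([[1.5, 700.0], [1.2, 900.0]])
        assert select_best(pairs2, np.array([1.0, 1.0])) == 1


class TestObservationSet:
    def _frame(self):
        return pd.DataFrame({
            "site_id": ["a", "a", "b", "b"],
            "biome": ["grass"] * 4,
            "depth_class": ["surface", "surface", "surface", "subsurface"],
            "date": ["2000-03-01", "2000-09-01", "2000-03-01", "2000-09-01"],
            "doc_mg_per_l": [10.0, 12.0, 8.0, 3.0],
        })

    def test_roundtrip_and_views(self, tmp_path):
        obs = ObservationSet(self._frame())
        assert obs.sites == ["a", "b"]
        assert len(obs.surface()) == 3
        path = tmp_path / "obs.csv"
        obs.to_csv(path)
        again = ObservationSet.from_csv(path)
        pd.testing.assert_frame_equal(
            obs.records.reset_index(drop=True), again.records.reset_index(drop=True))

    def test_single_measurement_site_rejected(self):
        df = self._frame().iloc[:3]  # site b keeps one record
        with pytest.raises(InvalidInputError, match="fewer than two"):
            ObservationSet(df)

    def test_nonpositive_concentration_rejected(self):
        df = self._frame()
        df.loc[0, "doc_mg_per_l"] = 0.0
        with pytest.raises(InvalidInputError):
            ObservationSet(df)

    def test_cell_aggregation_averages(self):
        df = self._frame()
        df["cell_id"] = ["c1", "c1", "c1", "c1"]
        merged = ObservationSet(df).aggregate_by_cell()
        rec = merged.records
        surf_march = rec[(rec["site_id"] == "c1")
                         & (rec["date"] == pd.Timestamp("2000-03-01"))]["doc_mg_per_l"]
        assert float(surf_march.iloc[0]) == pytest.approx(9.0)  # mean of 10 and 8


def test_match_observations_by_calendar_day():
    times = pd.date_range("2001-01-01", periods=365, freq="D")
    conc = np.arange(365, dtype=float)
    obs = pd.DataFrame({"date": ["1999-02-01", "2003-12-31"],
                        "doc_mg_per_l": [1.0, 2.0]})
    sim, ov = match_observations(times, conc, obs)
    assert sim[0] == 31.0   # Feb 1 is day index 31
    assert sim[1] == 364.0


@pytest.fixture(scope="module")
def setup():
    sc = synthetic.default_scenario("grass", t_mean=292.0, years=1, seed=2,
                                    n_sites=4, n_dates=6, obs_sigma=0.0)
    bounds = CalibrationBounds.for_biome("grass")
    pairs = latin_hypercube_sample(bounds, 9, seed=2)
    truth_idx = 4
    truth = sd.default_params("grass").replace(
        kp=float(pairs[truth_idx, 0]), kdoc_recalcitrant=float(pairs[truth_idx, 1]))
    forcings = synthetic.site_forcings(sc)
    obs = synthetic.generate_observations(truth, forcings, sc)
    return sc, bounds, pairs, truth_idx, forcings, obs


class TestCalibrateBiome:

    def test_noise_free_truth_in_candidate_set_is_selected(self, setup):
        sc, bounds, pairs, truth_idx, forcings, obs = setup
        res = calibration.calibrate_biome(obs, forcings, bounds=bounds,
                                          n_samples=9, k=2, seed=2)
        np.testing.assert_array_equal(res.pairs, pairs)  # same seed, same design
        assert res.best_index == truth_idx
        assert res.best_rmse == pytest.approx(0.0, abs=1e-6)

    def test_objective_matches_recomputed_rmse(self, setup):
        sc, bounds, pairs, truth_idx, forcings, obs = setup
        res = calibration.calibrate_biome(obs, forcings, bounds=bounds,
                                          n_samples=9, k=2, seed=2)
        per_site = res.matched_best.groupby("site_id").apply(
            lambda g: rmse(g["simulated"], g["observed"]), include_groups=False)
        assert res.best_rmse == pytest.approx(float(per_site.mean()), rel=1e-12)

    def test_validation_close_to_calibration_without_noise(self, setup):
        sc, bounds, pairs, truth_idx, forcings, obs = setup
        res = calibration.calibrate_biome(obs, forcings, bounds=bounds,
                                          n_samples=9, k=2, seed=2)
        i = res.best_index
        gap = abs(np.nanmean(res.val_rmse[i]) - np.nanmean(res.cal_rmse[i]))
        assert gap == pytest.approx(0.0, abs=1e-6)

    def test_missing_forcing_names_site(self, setup):
        sc, bounds, pairs, truth_idx, forcings, obs = setup
        partial = {k: v for k, v in forcings.items() if k != "site01"}
        with pytest.raises(InvalidInputError, match="site01"):
            calibration.calibrate_biome(obs, partial, bounds=bounds, n_samples=3, k=2)

    def test_mixed_biomes_rejected(self, setup):
        sc, bounds, pairs, truth_idx, forcings, obs = setup
        df = obs.records.copy()
        df.loc[df["site_id"] == "site00", "biome"] = "boreal"
        with pytest.raises(InvalidInputError, match="per-biome"):
            calibration.calibrate_biome(ObservationSet(df), forcings, bounds=bounds,
                                        n_samples=3, k=2)
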