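"""Altered latitude, Sørensen, per-station beta, bagplot outliers, broken stick."""

import numpy as np
import pandas as pd
import pytest

from poleward import (
    altered_latitude,
    bag_outliers,
    fit_breakpoint,
    presence_absence,
    scenario_gap_fill,
    sorensen_matrix,
    station_beta,
)
from poleward.breakpoints import candidate_breakpoints, halfspace_depth
from poleward.errors import InputError, ScenarioError


class TestAlteredLatitude:
    @pytest.mark.parametrize(
        "lat,expected", [(90.0, 0.0), (0.0, 90.0), (-90.0, 180.0), (37.833, 52.167)]
    )
    def test_pole_equator_mapping(self, lat, expected):
        assert altered_latitude(lat) == pytest.approx(expected, abs=1e-12)

    def test_array_input(self):
        out = altered_latitude(np.array([90.0, -90.0]))
        assert list(out) == [0.0, 180.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            altered_latitude(91.0)


class TestPresenceAbsence:
    def test_strict_threshold(self):
        t = pd.DataFrame({"a": [5.0, 5.1, 0.0]})
        out = presence_absence(t, threshold=5.0)
        assert list(out["a"]) == [0, 1, 0]

    def test_default_positive(self):
        t = pd.DataFrame({"a": [0.0, 1e-9]})
        assert list(presence_absence(t)["a"]) == [0, 1]

    def test_negative_threshold_rejected(self):
        with pytest.raises(InputError):
            presence_absence(pd.DataFrame({"a": [1.0]}), threshold=-1)


class TestSorensen:
    def test_identical_and_disjoint(self):
        pa = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b", "c"]
        )
        d = sorensen_matrix(pa)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_hand_counted_value(self):
        # a = 2 shared, b = c = 1 unique each: (1+1)/(4+1+1) = 1/3
        pa = pd.DataFrame([[1, 1, 1, 0], [1, 1, 0, 1]], index=["i", "j"])
        assert sorensen_matrix(pa).loc["i", "j"] == pytest.approx(1 / 3)

    def test_matches_set_arithmetic_oracle(self, rng):
        pa = pd.DataFrame((rng.random((7, 12)) < 0.5).astype(int))
        pa.iloc[:, 0] = 1  # no empty stations
        d = sorensen_matrix(pa)
        B = pa.to_numpy().astype(bool)
        for i in range(7):
            for j in range(7):
                a = int((B[i] & B[j]).sum())
                b = int((B[i] & ~B[j]).sum())
                c = int((~B[i] & B[j]).sum())
                expect = 0.0 if (b + c) == 0 else (b + c) / (2 * a + b + c)
                assert d.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_empty_station_named(self):
        pa = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "void"])
        with pytest.raises(InputError, match="void"):
            sorensen_matrix(pa)


class TestStationBeta:
    def test_identical_stations_all_zero(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        assert np.allclose(station_beta(d), 0.0)

    def test_one_disjoint_station(self):
        # Station d disjoint from 3 identical stations: its beta 1, others 1/3.
        D = np.zeros((4, 4))
        D[3, :3] = D[:3, 3] = 1.0
        beta = station_beta(pd.DataFrame(D, index=list("abcd"), columns=list("abcd")))
        assert beta["d"] == pytest.approx(1.0)
        assert beta["a"] == pytest.approx(1 / 3)

    def test_values_bounded(self, rng):
        M = rng.uniform(0, 1, (6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        for reduction in ("mean", "nearest", "adjacent"):
            b = station_beta(pd.DataFrame(D), reduction=reduction)
            assert b.between(0, 1).all()

    def test_too_few_stations_rejected(self):
        with pytest.raises(InputError):
            station_beta(pd.DataFrame(np.zeros((2, 2))))


class TestBagOutliers:
    def test_far_point_flagged(self, rng):
        x = np.r_[rng.normal(0, 1, 30), 100.0]
        y = np.r_[rng.normal(0, 1, 30), 100.0]
        mask = bag_outliers(x, y)
        assert mask[-1]
        assert mask[:-1].sum() == 0

    def test_uniform_grid_has_no_outliers(self):
        g = np.linspace(0, 1, 5)
        X, Y = np.meshgrid(g, g)
        mask = bag_outliers(X.ravel(), Y.ravel())
        assert mask.sum() == 0

    def test_small_sample_disabled_with_warning(self):
        with pytest.warns(UserWarning):
            mask = bag_outliers(np.arange(5.0), np.arange(5.0))
        assert mask.sum() == 0

    def test_gaussian_cloud_depths_match_direction_enumeration_oracle(self, rng):
        P = rng.normal(size=(60, 2))
        depths = halfspace_depth(P)
        # Oracle: enumerate unit normals of all point pairs (both nudges).
        eps = 1e-9
        diffs = P[:, None, :] - P[None, :, :]
        diffs = diffs.reshape(-1, 2)
        diffs = diffs[np.hypot(diffs[:, 0], diffs[:, 1]) > 0]
        ang = np.arctan2(diffs[:, 1], diffs[:, 0])
        cand = np.concatenate([ang + np.pi / 2 + eps, ang + np.pi / 2 - eps,
                               ang - np.pi / 2 + eps, ang - np.pi / 2 - eps])
        dirs = np.stack([np.cos(cand), np.sin(cand)], axis=1)
        for idx in range(0, 60, 7):
            p = P[idx]
            side = (P - p) @ dirs.T >= -1e-12
            assert depths[idx] == side.sum(axis=0).min()
        mask = bag_outliers(P[:, 0], P[:, 1])
        assert mask.mean() < 0.05


class TestFitBreakpoint:
    @staticmethod
    def exhaustive_oracle(x, y, search_range=None, min_segment=3):
        """Independent candidate loop using lstsq on an explicit design."""
        best = (None, np.inf, None)
        for psi in candidate_breakpoints(np.asarray(x, float), search_range, min_segment):
            X = np.column_stack([np.ones(len(x)), x, np.clip(np.asarray(x) - psi, 0, None)])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ coef) ** 2))
            if sse < best[1]:
                best = (float(psi), sse, coef)
        return best

    def test_noiseless_hinge_recovered(self):
        x = np.linspace(0, 20, 41)
        y = 1 + 0.5 * x - 0.7 * np.clip(x - 10, 0, None)
        fit = fit_breakpoint(x, y)
        gap = np.diff(np.unique(x)).max()
        assert abs(fit.psi - 10.0) <= gap / 2 + 1e-9
        assert fit.slope_change == pytest.approx(-0.7, abs=0.05)
        assert fit.slope == pytest.approx(0.5, abs=0.02)

    def test_matches_exhaustive_candidate_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 40))
            x = np.sort(rng.uniform(0, 10, n))
            y = rng.normal(size=n)
            fit = fit_breakpoint(x, y)
            psi_o, sse_o, _ = self.exhaustive_oracle(x, y)
            assert fit.psi == pytest.approx(psi_o)
            assert fit.mse * n == pytest.approx(sse_o, rel=1e-9)

    def test_straight_line_with_noise_is_not_significant(self, rng):
        x = np.linspace(0, 10, 50)
        y = 2 + 0.3 * x + rng.normal(0, 0.2, 50)
        fit = fit_breakpoint(x, y)
        assert fit.p_value > 0.05

    def test_shift_and_scale_invariance(self, rng):
        x = np.sort(rng.uniform(0, 20, 30))
        y = 1 + 0.4 * x - 0.9 * np.clip(x - 8, 0, None) + rng.normal(0, 0.05, 30)
        base = fit_breakpoint(x, y)
        shifted = fit_breakpoint(x, y + 11.0)
        assert shifted.psi == pytest.approx(base.psi)
        scaled = fit_breakpoint(3.0 * x, y)
        assert scaled.psi == pytest.approx(3.0 * base.psi, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            fit_breakpoint(np.ones(20), np.arange(20.0))

    def test_planted_transect_threshold_recovered(self):
        import poleward as pw
        from poleward.pipeline import breakpoint_analysis

        data = pw.simulate_transect(pw.TransectConfig(seed=7, threshold_T=14.0, noise_sd=0.2))
        res = breakpoint_analysis(
            pw.hits_per_million(data.table_18S), data.env, search_range=(7, 29.02)
        )
        assert abs(res["psi"] - 14.0) <= 1.5


class TestScenarioGapFill:
    @staticmethod
    def _setup():
        idx = [f"s{i}" for i in range(8)]
        env = pd.DataFrame({"latitude": [70, 60, 50, 40, 30, 20, 10, 0]}, index=idx)
        beta = pd.Series(np.linspace(1.0, 0.3, 8), index=idx)
        return env, beta

    def test_tie_goes_to_northern_donor(self):
        env, beta = self._setup()
        # s2 (lat 50) equidistant between donors s1 (60) and s3 (40).
        filled = scenario_gap_fill(beta, env, ["s2"], strategy="nearest_latitude")
        assert filled["s2"] == beta["s1"]

    def test_single_donor_region_fills_all_gaps(self):
        env, beta = self._setup()
        filled = scenario_gap_fill(
            beta, env, ["s3", "s4"], strategy="donor_region_A", donor_regions={"A": ["s0"]}
        )
        assert filled["s3"] == beta["s0"] and filled["s4"] == beta["s0"]

    def test_empty_donor_pool_rejected(self):
        env, beta = self._setup()
        with pytest.raises(ScenarioError):
            scenario_gap_fill(beta, env, ["s1"], strategy="donor_region_B", donor_regions={"B": []})

    def test_four_scenarios_give_distinct_filled_series(self, rng):
        idx = [f"s{i}" for i in range(20)]
        env = pd.DataFrame({"latitude": np.linspace(80, -80, 20)}, index=idx)
        beta = pd.Series(rng.uniform(0.2, 0.9, 20), index=idx)
        gaps = ["s7", "s8", "s9"]
        regions = {"A": ["s0", "s1", "s2"], "B": ["s17", "s18", "s19"]}
        fills = {
            s: scenario_gap_fill(beta, env, gaps, strategy=s, donor_regions=regions)
            for s in ("nearest_latitude", "donor_region_A", "donor_region_B", "both_donors")
        }
        gap_values = {s: tuple(f[gaps]) for s, f in fills.items()}
        assert len(set(gap_values.values())) >= 3  # scenarios generally differ
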