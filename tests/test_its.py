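import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gpprenatal import (
    RateParams,
    ValidationError,
    coefficient_recovery_study,
    compare_to_baseline,
    compute_daily_rates,
    fit_segment,
    run_its,
    simulate_rate_series,
    smooth_centered,
)
from gpprenatal.phases import build_phase_calendar
from gpprenatal.its import add_smoothed

from _oracles import moving_average_loop, ols_normal_equations

THREE_PHASES = {
    "0": [(2019, 1, 52), (2020, 1, 8)],
    "1a": [(2020, 9, 13)],
    "1b": [(2020, 14, 22), (2020, 23, 53), (2021, 1, 52)],
}


def _segment(t, seasons, y, subphase="0"):
    return pd.DataFrame({
        "subphase": subphase, "t_days": t, "season": seasons, "rate": y})


class TestDailyRates:
    def test_rate_arithmetic(self, calendar):
        d0, d1 = calendar["date"].iloc[0], calendar["date"].iloc[1]
        contacts = pd.DataFrame({
            "contact_id": [f"C{i}" for i in range(5)],
            "patient_id": "P1", "date": [d1] * 5})
        series = compute_daily_rates(contacts, {d: 500 for d in calendar["date"]},
                                     calendar.head(10))
        assert series.loc[series["date"] == d0, "rate"].iloc[0] == 0.0
        assert series.loc[series["date"] == d1, "rate"].iloc[0] == 10.0

    def test_zero_denominator_with_contacts_names_date(self, calendar):
        d = calendar["date"].iloc[0]
        contacts = pd.DataFrame({"contact_id": ["C1"], "patient_id": ["P1"], "date": [d]})
        with pytest.raises(ValidationError, match=str(d)):
            compute_daily_rates(contacts, {}, calendar.head(5))

    def test_mean_rate_tracks_generating_intensity(self):
        """Constant generating intensity 10/1000: the mean raw rate stays
        inside the Poisson-derived 99% band of 10."""
        from scipy import stats

        cal = build_phase_calendar({"0": [(2019, 1, 52), (2020, 1, 53), (2021, 1, 52)]})
        sim = simulate_rate_series({"0": RateParams(10.0, 0.0, {})}, cal, 1000,
                                   np.random.default_rng(3))
        contacts = pd.DataFrame({
            "contact_id": range(int(sim["n_contacts"].sum())),
            "patient_id": "P",
            "date": np.repeat(sim["date"].to_numpy(),
                              sim["n_contacts"].astype(int).to_numpy())})
        series = compute_daily_rates(contacts, {d: 1000 for d in cal["date"]}, cal)
        n = len(series)
        total = series["n_contacts"].sum()
        lo = stats.poisson.ppf(0.005, 10 * n)
        hi = stats.poisson.ppf(0.995, 10 * n)
        assert lo <= total <= hi
        assert series["rate"].mean() == pytest.approx(1000 * total / 1000 / n)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        out = smooth_centered([3.0] * 20, 15)
        assert np.allclose(out, 3.0)

    def test_window_one_is_identity(self):
        y = [1.0, 5.0, 2.0, 8.0]
        assert np.allclose(smooth_centered(y, 1), y)

    def test_spike_example(self):
        out = smooth_centered([0, 0, 0, 15, 0, 0, 0], 3)
        assert np.allclose(out, [0, 0, 5, 5, 5, 0, 0])

    def test_even_window_rejected(self):
        with pytest.raises(Exception):
            smooth_centered([1.0, 2.0], 4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
        half=st.integers(0, 10),
    )
    def test_matches_brute_force_loop(self, y, half):
        window = 2 * half + 1
        assert np.allclose(smooth_centered(y, window),
                           moving_average_loop(y, window))

    def test_within_subphase_scope_restarts(self, calendar):
        rng = np.random.default_rng(0)
        sub = calendar.head(40).copy()
        sub["rate"] = rng.normal(10, 1, size=40)
        glob = add_smoothed(sub, 15, "global")
        within = add_smoothed(sub.assign(
            subphase=["A"] * 20 + ["B"] * 20), 15, "within_subphase")
        # interior of the first block must differ near the boundary
        assert not np.allclose(glob["smoothed"].iloc[15:25],
                               within["smoothed"].iloc[15:25])


class TestFitSegment:
    def test_noise_free_recovery_exact(self):
        """Y = 10 + 0.05 t + 0.5*summer over a spring+summer span is recovered
        exactly (closed-form normal equations agree to 1e-8)."""
        t = np.arange(60, dtype=float)
        seasons = ["spring"] * 30 + ["summer"] * 30
        y = 10 + 0.05 * t + 0.5 * (np.arange(60) >= 30)
        fit = fit_segment(_segment(t, seasons, y), response="rate")
        assert fit.params["intercept"] == pytest.approx(10.0, abs=1e-8)
        assert fit.params["slope"] == pytest.approx(0.05, abs=1e-8)
        assert fit.params["summer"] == pytest.approx(0.5, abs=1e-8)
        assert fit.absent_seasons == ("winter", "autumn")

    def test_constant_series_degenerate_r_squared(self):
        fit = fit_segment(_segment(np.arange(10.0), ["spring"] * 10, [4.0] * 10),
                          response="rate")
        assert fit.params["intercept"] == pytest.approx(4.0)
        assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(fit.r_squared) and np.isnan(fit.adj_r_squared)

    def test_spring_absent_rereferences_to_first_season(self):
        """A summer+autumn subphase absorbs summer into the intercept."""
        t = np.arange(40, dtype=float)
        seasons = ["summer"] * 20 + ["autumn"] * 20
        y = 8.0 + 0.1 * t - 0.3 * (np.arange(40) >= 20)
        fit = fit_segment(_segment(t, seasons, y), response="rate")
        assert fit.reference_season == "summer"
        assert fit.params["intercept"] == pytest.approx(8.0, abs=1e-8)
        assert fit.params["autumn"] == pytest.approx(-0.3, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        """OLS path equals the closed-form solver on random small designs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        t = np.sort(rng.uniform(0, 90, n))
        seasons = rng.choice(["spring", "summer", "autumn", "winter"], n)
        if len(set(seasons)) < 2:  # keep the design full rank
            seasons[0] = "spring"
        y = rng.normal(10, 2, n)
        fit = fit_segment(_segment(t, list(seasons), y), response="rate")
        cols = [np.ones(n), t]
        for s in ("winter", "summer", "autumn"):
            if s in fit.params:
                cols.append((seasons == s).astype(float))
        X = np.column_stack(cols)
        beta, se, r2, adj = ols_normal_equations(X, y)
        names = [k for k in fit.params]
        assert np.allclose([fit.params[k] for k in names], beta, atol=1e-8)
        assert np.allclose([fit.se[k] for k in names], se, atol=1e-8)
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)
        assert fit.adj_r_squared == pytest.approx(adj, abs=1e-8)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            fit_segment(_segment([0.0, 1.0], ["spring", "spring"], [1.0, 2.0]),
                        response="rate")


class TestBaselineComparison:
    def test_identical_fits_give_z_zero_p_one(self):
        t = np.arange(30, dtype=float)
        y = 10 + 0.02 * t
        f = fit_segment(_segment(t, ["spring"] * 30, y + np.sin(t)), response="rate")
        out = compare_to_baseline(f, f, "slope")
        assert out["z"] == 0.0 and out["p_value"] == 1.0

    def test_z_and_p_match_normal_cdf(self):
        from gpprenatal.its import SegmentFit

        fp = SegmentFit("1a", {"intercept": 1.0}, {"intercept": 0.1}, 10, 0.5, 0.4)
        f0 = SegmentFit("0", {"intercept": 0.5}, {"intercept": 0.1}, 10, 0.5, 0.4)
        out = compare_to_baseline(fp, f0, "intercept")
        assert out["z"] == pytest.approx(3.5355339, abs=1e-6)
        assert out["p_value"] == pytest.approx(4.0695e-4, rel=1e-3)

    def test_antisymmetry(self):
        from gpprenatal.its import SegmentFit

        rng = np.random.default_rng(1)
        for _ in range(20):
            b = rng.normal(size=2)
            s = rng.uniform(0.01, 1, size=2)
            fa = SegmentFit("a", {"slope": b[0]}, {"slope": s[0]}, 9, 0.1, 0.1)
            fb = SegmentFit("b", {"slope": b[1]}, {"slope": s[1]}, 9, 0.1, 0.1)
            assert compare_to_baseline(fa, fb, "slope")["z"] == pytest.approx(
                -compare_to_baseline(fb, fa, "slope")["z"])

    def test_missing_parameter_rejected(self):
        from gpprenatal.its import SegmentFit

        fa = SegmentFit("a", {"intercept": 1.0}, {"intercept": 0.1}, 9, 0.1, 0.1)
        fb = SegmentFit("b", {"intercept": 1.0, "winter": 0.2},
                        {"intercept": 0.1, "winter": 0.1}, 9, 0.1, 0.1)
        with pytest.raises(ValidationError):
            compare_to_baseline(fa, fb, "winter")


class TestRunIts:
    def test_three_subphase_layout(self):
        """3 subphases yield 3 fits and 2 pandemic x 2 parameters = 4
        comparisons; the baseline is never compared with itself."""
        cal = build_phase_calendar(THREE_PHASES)
        params = {s: RateParams(10.0, 0.0, {}) for s in THREE_PHASES}
        sim = simulate_rate_series(params, cal, 5000, np.random.default_rng(2))
        contacts = pd.DataFrame({
            "contact_id": range(int(sim["n_contacts"].sum())),
            "patient_id": "P",
            "date": np.repeat(sim["date"].to_numpy(),
                              sim["n_contacts"].astype(int).to_numpy())})
        fits, comps = run_its(contacts, {d: 5000 for d in cal["date"]}, cal)
        assert len(fits) == 3
        assert len(comps) == 4
        assert "0" not in set(comps["subphase"])
        assert set(comps["parameter"]) == {"intercept", "slope"}

    def test_deterministic_rerun(self, calendar):
        rng = np.random.default_rng(8)
        sim = simulate_rate_series(
            {s: RateParams(10, 0.0, {}) for s in calendar["subphase"].unique()},
            calendar, 2000, rng)
        contacts = pd.DataFrame({
            "contact_id": range(int(sim["n_contacts"].sum())),
            "patient_id": "P",
            "date": np.repeat(sim["date"].to_numpy(),
                              sim["n_contacts"].astype(int).to_numpy())})
        den = {d: 2000 for d in calendar["date"]}
        f1, c1 = run_its(contacts, den, calendar)
        f2, c2 = run_its(contacts, den, calendar)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(c1, c2)


class TestRecovery:
    def test_noise_free_coefficients_recovered(self):
        from gpprenatal.config import DEFAULT_PHASE_RATE_PARAMS

        res = coefficient_recovery_study(
            DEFAULT_PHASE_RATE_PARAMS, n_replicates=2, seed=0, noise=False)
        assert res["max_abs_error"] < 1e-6

    def test_noisy_coverage_reasonable(self):
        """Short sanity run; the full 100-replicate coverage check lives in the
        acceptance suite."""
        from gpprenatal.config import DEFAULT_PHASE_RATE_PARAMS

        res = coefficient_recovery_study(
            DEFAULT_PHASE_RATE_PARAMS, n_replicates=10, seed=0)
        assert res["coverage"]["overall"] >= 0.85
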