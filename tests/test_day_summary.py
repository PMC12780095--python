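from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

import accelmort.day_summary as ds
from accelmort.epoch_measures import EpochSeries, MEASURES
from accelmort.signal_preprocess import CalibrationResult, IMPUTED, NONWEAR, WEAR
from accelmort.synthetic_data import (ActivityProfile, SimulationConfig,
                                      generate_epoch_series)
from oracles import loglog_leastsquares

T0 = datetime(2015, 6, 1, 0, 0, 0)
SPD = 17280  # 5 s slots per day


def make_series(values_per_day: list[np.ndarray],
                flags_per_day: list[np.ndarray] | None = None,
                pid: str = "P0000") -> EpochSeries:
    values = np.concatenate(values_per_day)
    n = values.size
    flags = (np.concatenate(flags_per_day) if flags_per_day
             else np.full(n, WEAR, dtype=np.int8))
    vals = {m: values.copy() for m in MEASURES}
    return EpochSeries(pid, T0, 5.0, vals, flags)


class TestImputation:
    def test_two_point_mean_at_slot(self):
        days = [np.full(SPD, 10.0), np.full(SPD, 99.0), np.full(SPD, 20.0)]
        flags = [np.full(SPD, WEAR, dtype=np.int8) for _ in range(3)]
        noon = 12 * 720  # slot of 12:00:00
        flags[1][noon] = NONWEAR
        out = ds.impute_invalid(make_series(days, flags))
        assert out.values["enmo"][SPD + noon] == pytest.approx(15.0)
        assert out.flags[SPD + noon] == IMPUTED
        assert out.has_value[SPD + noon]

    def test_identity_when_no_invalid(self):
        series = make_series([np.arange(SPD, dtype=float)] * 2)
        out = ds.impute_invalid(series)
        for m in MEASURES:
            np.testing.assert_array_equal(out.values[m], series.values[m])
        np.testing.assert_array_equal(out.flags, series.flags)

    def test_slot_invalid_everywhere_breaks_coverage(self):
        days = [np.full(SPD, 10.0)] * 3
        flags = [np.full(SPD, WEAR, dtype=np.int8) for _ in range(3)]
        noon = 12 * 720
        for f in flags:
            f[noon] = NONWEAR
        out = ds.impute_invalid(make_series(days, flags))
        assert not out.has_value[noon]
        periods = ds.coverage_by_period(out)
        assert periods.sum() == 95
        assert not periods[noon // 180]

    def test_single_day_no_imputation(self):
        flags = [np.full(SPD, WEAR, dtype=np.int8)]
        flags[0][100] = NONWEAR
        out = ds.impute_invalid(make_series([np.full(SPD, 5.0)], flags))
        assert not out.has_value[100]


class TestValidDays:
    def test_full_day_valid_and_16h_exactly_invalid(self):
        full = np.full(SPD, WEAR, dtype=np.int8)
        exactly_16h = np.full(SPD, NONWEAR, dtype=np.int8)
        exactly_16h[: 16 * 720] = WEAR
        series = make_series([np.zeros(SPD)] * 2, [full, exactly_16h])
        days = ds.valid_day_flags(series)
        assert days[0].valid
        assert days[0].wear_hours == pytest.approx(24.0)
        assert not days[1].valid          # strict > 16 h
        assert days[1].wear_hours == pytest.approx(16.0)

    def test_imputed_epochs_do_not_count_as_wear(self):
        # 15 h wear + the rest imputable from a full neighbouring day
        partial = np.full(SPD, NONWEAR, dtype=np.int8)
        partial[: 15 * 720] = WEAR
        full = np.full(SPD, WEAR, dtype=np.int8)
        series = make_series([np.zeros(SPD)] * 2, [partial, full])
        imputed = ds.impute_invalid(series)
        days = ds.valid_day_flags(imputed)
        assert days[0].wear_hours == pytest.approx(15.0)
        assert not days[0].valid
        assert days[1].valid


class TestAvAcc:
    def test_closed_forms_and_order_invariance(self, rng):
        v = np.full(SPD, 30.0)
        has = np.ones(SPD, dtype=bool)
        assert ds.average_acceleration(v, has) == pytest.approx(30.0)
        v2 = np.concatenate([np.zeros(SPD // 2), np.full(SPD // 2, 60.0)])
        assert ds.average_acceleration(v2, has) == pytest.approx(30.0)
        perm = rng.permutation(SPD)
        assert ds.average_acceleration(v2[perm], has) == pytest.approx(30.0)


class TestBinAdjustment:
    def setup_method(self):
        self.ref_scheme = ds.reference_enmo_bins()
        rng = np.random.default_rng(7)
        self.ref = rng.uniform(1.0, 500.0, size=10_000)

    def test_identity_pairing(self):
        scheme = ds.build_bins("mad", self.ref_scheme, self.ref, self.ref.copy())
        a, b = ds.fit_power_map(self.ref, self.ref)
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(scheme.edges, self.ref_scheme.edges)

    def test_exact_doubling(self):
        scheme = ds.build_bins("mad", self.ref_scheme, self.ref, 2 * self.ref)
        a, b = ds.fit_power_map(self.ref, 2 * self.ref)
        assert (a, b) == (pytest.approx(2.0), pytest.approx(1.0))
        np.testing.assert_allclose(scheme.edges, 2 * self.ref_scheme.edges)

    def test_power_exponent_recovery_with_noise(self):
        rng = np.random.default_rng(42)
        target = self.ref ** 1.2 * np.exp(rng.normal(0, 0.05, self.ref.size))
        a, b = ds.fit_power_map(self.ref, target)
        a_o, b_o = loglog_leastsquares(self.ref, target)
        assert b == pytest.approx(b_o, abs=1e-12)
        assert abs(b - 1.2) < 0.02

    def test_degenerate_fit_falls_back_to_quantiles(self):
        rng = np.random.default_rng(3)
        target = rng.uniform(1, 2, self.ref.size)  # unrelated -> b ~ 0
        scheme = ds.build_bins("mims", self.ref_scheme, self.ref, target)
        assert getattr(scheme, "fallback", False)
        assert np.all(np.diff(scheme.edges) > 0)


class TestIntensityGradient:
    def test_exact_power_law_occupancy(self):
        # occupancy t_b = C * x_b^(-2) held exactly (integer epoch counts on
        # geometric midpoints) -> slope -2.000, R^2 = 1
        mids = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        edges = np.array([0.5, 1.5, 3.0, 6.0, 12.0, 24.0, 48.0])
        scheme = ds.BinScheme("enmo", edges, mids)
        counts = (1024 / mids ** 2).astype(int)       # 1024, 256, ..., 1
        values = np.repeat(mids, counts)
        slope, intercept, r2 = ds.intensity_gradient(values, scheme)
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_line_without_rounding(self):
        scheme = ds.BinScheme("enmo", np.arange(0, 525, 25.0),
                              np.arange(12.5, 500, 25.0))
        k = np.arange(scheme.n_bins)
        values = np.repeat(scheme.midpoints, 5 * (k + 1) ** 0)  # equal time
        slope, _, _ = ds.intensity_gradient(values, scheme)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_generator_day_recovers_power_law_slope(self):
        cfg = SimulationConfig(
            n_participants=1, n_days=1, seed=99,
            activity=ActivityProfile(rest_fraction=0.0, burst_intensity_law=2.5),
            rest_fraction_sd=0.0, alpha_sd=0.0,
            epoch_intensity_range_mg=(25.0, 2000.0))
        series = generate_epoch_series(cfg, 0)
        scheme = ds.reference_enmo_bins()
        slope, _, r2 = ds.intensity_gradient(series.values["enmo"], scheme)
        assert abs(slope - (-2.5)) < 0.15

    def test_too_few_bins_undefined(self):
        scheme = ds.reference_enmo_bins()
        slope, _, _ = ds.intensity_gradient(np.full(1000, 12.0), scheme)
        assert np.isnan(slope)

    def test_permutation_invariance(self, rng):
        scheme = ds.reference_enmo_bins()
        values = rng.uniform(0, 3000, size=SPD)
        a = ds.intensity_gradient(values, scheme)
        b = ds.intensity_gradient(values[rng.permutation(SPD)], scheme)
        assert a == b

    def test_scale_covariance(self, rng):
        values = rng.uniform(10, 3000, size=SPD)
        scheme = ds.reference_enmo_bins()
        c = 37.5
        scaled = ds.BinScheme("mad", scheme.edges * c, scheme.midpoints * c)
        s1, _, _ = ds.intensity_gradient(values, scheme)
        s2, _, _ = ds.intensity_gradient(values * c, scaled)
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestParticipantSummary:
    def _days(self, avaccs, igs=None, valid=True):
        out = []
        for i, a in enumerate(avaccs):
            d = ds.DaySummary(date=None, wear_hours=24.0, coverage_ok=True,
                              valid=valid)
            d.avacc = {m: a for m in MEASURES}
            ig = igs[i] if igs else -2.5
            d.ig_slope = {m: ig for m in MEASURES}
            out.append(d)
        return out

    def test_mean_over_valid_days(self):
        s = ds.summarise_participant("P1", self._days([20.0, 25.0, 30.0]))
        assert s.avacc["enmo"] == pytest.approx(25.0)
        assert not s.excluded

    def test_ig_undefined_day_skipped(self):
        days = self._days([20.0] * 4, igs=[-2.0, -3.0, float("nan"), -4.0])
        s = ds.summarise_participant("P1", days)
        assert s.ig["enmo"] == pytest.approx(-3.0)

    def test_two_valid_days_excluded(self):
        s = ds.summarise_participant("P1", self._days([20.0, 25.0]))
        assert s.excluded and s.exclusion_reason == "valid_days"


class TestExclusions:
    def _summary(self, pid, avacc, ig=-2.5, n_days=5):
        return ds.ParticipantSummary(pid, n_days,
                                     {m: avacc for m in MEASURES},
                                     {m: ig for m in MEASURES})

    def test_calibration_threshold(self):
        # identical exposures so the percentile trim cannot fire
        s = [self._summary(f"P{i}", 25.0) for i in range(20)]
        calibs = {"P0": CalibrationResult(np.ones(3), np.zeros(3), 0.02, 50)}
        out = ds.apply_exclusions(s, calibs)
        assert out[0].exclusion_reason == "calibration"
        assert all(not x.excluded for x in out[1:])

    def test_avacc_boundary_100_retained(self):
        s = [self._summary(f"P{i}", v) for i, v in
             enumerate([100.0] + [25.0 + i * 0.685 for i in range(20)])]
        out = ds.apply_exclusions(s, {})
        assert out[0].exclusion_reason != "avacc_gt_100"
        s2 = [self._summary("X", 100.001)] + s[1:]
        out2 = ds.apply_exclusions(s2, {})
        assert out2[0].exclusion_reason == "avacc_gt_100"

    def test_percentile_trim_matches_bruteforce(self, rng):
        n = 1000
        s = [self._summary(f"P{i:04d}", av, ig) for i, (av, ig) in
             enumerate(zip(rng.normal(25, 5, n), rng.normal(-2.5, 0.3, n)))]
        out = ds.apply_exclusions(s, {})
        trimmed = [x for x in out if x.exclusion_reason == "percentile_trim"]
        assert 0 < len(trimmed) <= 20       # at most 2%
        # brute-force recount with an independent percentile computation
        av = np.sort([x.avacc["enmo"] for x in s])
        ig = np.sort([x.ig["enmo"] for x in s])

        def pct(sorted_v, q):
            idx = (len(sorted_v) - 1) * q / 100.0
            lo, hi = int(np.floor(idx)), int(np.ceil(idx))
            frac = idx - lo
            return sorted_v[lo] * (1 - frac) + sorted_v[hi] * frac

        brute = {x.participant_id for x in s
                 if x.avacc["enmo"] < pct(av, 0.5)
                 or x.avacc["enmo"] > pct(av, 99.5)
                 or x.ig["enmo"] < pct(ig, 0.5)
                 or x.ig["enmo"] > pct(ig, 99.5)}
        assert {x.participant_id for x in trimmed} == brute

    def test_shared_survivor_set(self, rng):
        n = 200
        s = [self._summary(f"P{i:04d}", av) for i, av in
             enumerate(rng.normal(25, 5, n))]
        out = ds.apply_exclusions(s, {})
        frame = ds.summaries_to_frame(out)
        survivors = frame[~frame["excluded"]]
        # one shared set: per-measure columns all present for every survivor
        for m in MEASURES:
            col = [c for c in frame.columns if c.startswith(f"avacc_{m}")][0]
            assert survivors[col].notna().all()

    def test_empty_survivor_set_aborts(self):
        s = [ds.ParticipantSummary("P1", 1, {m: 25.0 for m in MEASURES},
                                   {m: -2.5 for m in MEASURES},
                                   True, "valid_days")]
        with pytest.raises(RuntimeError):
            ds.apply_exclusions(s, {})
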