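"""Calibration fitting, LOD/LOQ, correction factors and peak location."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qams import (
    CalibrationCurve,
    PeakRecord,
    PeakTable,
    RCFEntry,
    RCFSet,
    RRTable,
    StandardSeries,
    compute_rcf,
    compute_rcf_set,
    compute_rrt,
    durability_rcf,
    estimate_lod_loq,
    fit_calibration,
    locate_peaks,
    reconstruct_linear_ranges,
)
from qams import synthetic_data as synth
from qams.calibration import DEFAULT_RETENTION_TIMES
from qams.errors import (
    InvalidInputError,
    PairingError,
    PeakLocationError,
    ZeroResponseError,
)


def ols_closed_form(x, y):
    """Independent least-squares oracle: direct normal-equation solution."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return slope, y.mean() - slope * x.mean()


class TestFitCalibration:
    def test_exact_line_recovers_printed_coefficients(self):
        conc = np.sort(209.6 / np.array([1, 2, 5, 10, 20, 50, 100]))
        series = StandardSeries("GC", tuple(conc),
                                tuple(1815300 * conc + 8028))
        curve = fit_calibration(series)
        assert curve.slope == pytest.approx(1815300)
        assert curve.intercept == pytest.approx(8028)
        assert curve.r == pytest.approx(1.0)
        assert curve.linear_range == (conc.min(), conc.max())

    def test_two_points_define_the_line(self):
        curve = fit_calibration(StandardSeries("X", (1, 2), (2, 4)))
        assert (curve.slope, curve.intercept) == (2.0, 0.0)
        assert curve.r == pytest.approx(1.0)

    def test_noisy_series_recovers_slope_within_2pct(self, truth):
        series = synth.make_standard_series(truth, seed=42)["GV"]
        curve = fit_calibration(series)
        assert curve.slope == pytest.approx(truth.slopes["GV"], rel=0.02)
        slope, intercept = ols_closed_form(series.concentrations, series.areas)
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0.1, 1e3), st.floats(1.0, 1e7)),
                    min_size=3, max_size=10, unique_by=lambda p: p[0]))
    def test_matches_closed_form_ols(self, points):
        points.sort()
        series = StandardSeries("X", tuple(p[0] for p in points),
                                tuple(p[1] for p in points))
        x = np.asarray(series.concentrations)
        if np.ptp(x) < 1e-6 * x.max():
            return  # numerically near-degenerate design, not a calibration
        slope, intercept = ols_closed_form(series.concentrations, series.areas)
        if slope <= 0:
            return  # response must rise with concentration to be a curve
        curve = fit_calibration(series)
        assert curve.slope == pytest.approx(slope, rel=1e-9)
        assert curve.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-6)

    def test_invalid_series_rejected(self):
        with pytest.raises(InvalidInputError):
            StandardSeries("X", (1.0,), (2.0,))
        with pytest.raises(InvalidInputError):
            StandardSeries("X", (1.0, 1.0), (2.0, 3.0))
        with pytest.raises(InvalidInputError):
            StandardSeries("X", (-1.0, 1.0), (2.0, 3.0))


class TestLodLoq:
    def test_zero_noise_gives_zero_limits(self, printed_curves):
        assert estimate_lod_loq(printed_curves["GC"], 0.0) == (0.0, 0.0)

    def test_direct_arithmetic(self, printed_curves):
        curve = printed_curves["GC"]
        lod, loq = estimate_lod_loq(curve, curve.slope / 30.0)
        assert lod == pytest.approx(0.1)
        assert loq == pytest.approx(1.0 / 3.0)

    def test_consistent_with_printed_scale(self, printed_curves):
        curve = printed_curves["GC"]
        lod, loq = estimate_lod_loq(curve, curve.slope * 0.29 / 3.0)
        assert lod == pytest.approx(0.29)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.0, 1e6), st.floats(1.0, 1e7))
    def test_scaling_laws(self, noise_sd, slope):
        curve = CalibrationCurve("X", slope, 0.0, 1.0, (1.0, 10.0))
        lod, loq = estimate_lod_loq(curve, noise_sd)
        assert loq == pytest.approx(lod * 10.0 / 3.0)
        lod2, _ = estimate_lod_loq(
            CalibrationCurve("X", 2 * slope, 0.0, 1.0, (1.0, 10.0)), noise_sd)
        assert lod2 == pytest.approx(lod / 2.0)

    def test_negative_noise_rejected(self, printed_curves):
        with pytest.raises(InvalidInputError):
            estimate_lod_loq(printed_curves["GC"], -1.0)


def _noiseless_series(slopes, intercepts=None):
    truth = synth.ResponseTruth(
        slopes=slopes,
        intercepts=intercepts or {c: 0.0 for c in slopes},
        retention_times={c: 10.0 + 5 * i for i, c in enumerate(slopes)},
        area_cv_pct=0.0, rt_jitter_sd_min=0.0)
    stocks = {c: 100.0 for c in slopes}
    return synth.make_standard_series(truth, stock_concentrations=stocks)


class TestRCF:
    def test_internal_vs_itself_is_identity(self, truth):
        series = synth.make_standard_series(truth, seed=3)["GV"]
        entry = compute_rcf(series, series)
        assert entry.mean_f == 1.0
        assert entry.rsd_f == 0.0
        assert set(entry.per_level_f) == {1.0}

    def test_zero_intercept_ratio_of_slopes(self):
        series = _noiseless_series({"S": 2.0, "K": 4.0})
        entry = compute_rcf(series["S"], series["K"])
        assert entry.per_level_f == tuple([0.5] * 7)
        assert entry.mean_f == pytest.approx(0.5)
        assert entry.rsd_f == pytest.approx(0.0, abs=1e-10)

    def test_printed_gc_factor_near_slope_ratio(self, truth):
        """The printed mean f for GC (1.047) is approximated to within 1% by
        the ratio of the printed GV and GC calibration slopes."""
        series = synth.make_standard_series(truth.noiseless())
        entry = compute_rcf(series["GV"], series["GC"])
        slope_ratio = truth.slopes["GV"] / truth.slopes["GC"]
        assert entry.mean_f == pytest.approx(slope_ratio, rel=0.005)
        assert abs(slope_ratio - 1.047) / 1.047 < 0.01

    def test_level_mismatch_and_zero_values(self):
        a = StandardSeries("A", (1, 2, 3), (10, 20, 30))
        b = StandardSeries("B", (1, 2), (10, 20))
        with pytest.raises(PairingError):
            compute_rcf(a, b)

    def test_rcf_set_requires_internal(self, truth):
        series = synth.make_standard_series(truth, seed=1)
        with pytest.raises(InvalidInputError):
            compute_rcf_set(series, "XX")
        rcf = compute_rcf_set(series, "GV")
        assert rcf.f("GV") == 1.0
        assert all(e.mean_f > 0 for e in rcf.entries.values())


def _rcf_set(mean_f_by_code):
    entries = {c: RCFEntry(c, (f,), f, 0.0) for c, f in mean_f_by_code.items()}
    return RCFSet("GV", entries)


class TestDurability:
    def test_identical_conditions_pass(self):
        sets = [_rcf_set({"GV": 1.0, "GC": 1.05})] * 3
        result = durability_rcf(sets)
        assert result.all_pass
        assert (result.table["rsd_pct"] == 0).all()

    def test_two_percent_spread_passes(self):
        sets = [_rcf_set({"GV": 1.0, "GC": f}) for f in (1.00, 1.02, 0.98)]
        result = durability_rcf(sets)
        assert result.table.loc["GC", "rsd_pct"] == pytest.approx(2.0)
        assert result.all_pass

    def test_twenty_percent_spread_fails(self):
        sets = [_rcf_set({"GV": 1.0, "GC": f}) for f in (1.0, 1.2, 0.8)]
        result = durability_rcf(sets)
        assert result.table.loc["GC", "rsd_pct"] == pytest.approx(20.0)
        assert not result.all_pass

    def test_mismatched_panels_rejected(self):
        with pytest.raises(InvalidInputError):
            durability_rcf([_rcf_set({"GV": 1.0, "GC": 1.0}),
                            _rcf_set({"GV": 1.0, "GH": 1.0})])


def _assigned_run(sample_id, times):
    peaks = tuple(PeakRecord(t, 1000.0, assigned_analyte=c)
                  for c, t in times.items())
    return PeakTable(sample_id, peaks)


class TestRRT:
    def test_single_run_offset(self):
        rrt = compute_rrt([_assigned_run("r1", {"GV": 20.0, "V": 25.5})], "GV")
        assert rrt.offsets["V"][0] == pytest.approx(5.5)
        assert rrt.offsets["GV"] == (0.0, 0.0)

    def test_cross_run_spread_matches_sample_statistics(self):
        deltas = [5.45, 5.48, 5.52, 5.55, 5.50]
        runs = [_assigned_run(f"r{i}", {"GV": 20.0, "V": 20.0 + d})
                for i, d in enumerate(deltas)]
        rrt = compute_rrt(runs, "GV")
        mean, spread = rrt.offsets["V"]
        assert mean == pytest.approx(np.mean(deltas))
        expected = 100 * np.std(deltas, ddof=1) / np.mean(deltas)
        assert spread == pytest.approx(expected)
        assert spread < 5.0  # the stability bound used for routine transfer

    def test_missing_reference_names_the_run(self):
        runs = [_assigned_run("good", {"GV": 20.0, "V": 25.5}),
                _assigned_run("bad", {"V": 25.5, "H": 40.0})]
        with pytest.raises(PeakLocationError, match="bad"):
            compute_rrt(runs, "GV")


@pytest.fixture()
def default_rrt():
    offsets = {c: (t - DEFAULT_RETENTION_TIMES["GV"], 0.0)
               for c, t in DEFAULT_RETENTION_TIMES.items()}
    return RRTable("GV", offsets, tolerance=0.5)


class TestLocatePeaks:
    def test_complete_assignment(self, default_rrt):
        table = PeakTable("s", tuple(
            PeakRecord(t, 100.0) for t in DEFAULT_RETENTION_TIMES.values()))
        located = locate_peaks(table, default_rrt, 20.0)
        assert located.absent == ()
        assigned = located.assigned()
        for code, t in DEFAULT_RETENTION_TIMES.items():
            assert assigned[code].retention_time == t

    def test_missing_peak_flagged_absent(self, default_rrt):
        times = {c: t for c, t in DEFAULT_RETENTION_TIMES.items() if c != "H"}
        table = PeakTable("s", tuple(PeakRecord(t, 1.0)
                                     for t in times.values()))
        located = locate_peaks(table, default_rrt, 20.0)
        assert located.absent == ("H",)
        assert len(located.assigned()) == 5

    def test_shift_beyond_tolerance_not_misassigned(self, default_rrt):
        times = dict(DEFAULT_RETENTION_TIMES)
        times["H"] = times["H"] + 2.0  # far outside the 0.5 min tolerance
        table = PeakTable("s", tuple(PeakRecord(t, 1.0)
                                     for t in times.values()))
        located = locate_peaks(table, default_rrt, 20.0)
        assert located.absent == ("H",)

    def test_idempotent(self, default_rrt):
        table = PeakTable("s", tuple(
            PeakRecord(t + 0.05, 9.0)
            for t in DEFAULT_RETENTION_TIMES.values()))
        once = locate_peaks(table, default_rrt, 20.0)
        twice = locate_peaks(once, default_rrt, 20.0)
        assert once == twice

    def test_competition_resolved_by_smallest_deviation(self):
        rrt = RRTable("GV", {"GV": (0.0, 0.0), "A": (5.0, 0.0),
                             "B": (5.2, 0.0)}, tolerance=0.5)
        # one candidate peak between the two expected offsets, nearer to B
        table = PeakTable("s", (PeakRecord(20.0, 1.0), PeakRecord(25.15, 1.0)))
        located = locate_peaks(table, rrt, 20.0)
        assert located.assigned()["B"].retention_time == 25.15
        assert located.absent == ("A",)

    def test_reference_not_found(self, default_rrt):
        table = PeakTable("s", (PeakRecord(5.0, 1.0),))
        with pytest.raises(PeakLocationError):
            locate_peaks(table, default_rrt, 20.0)


def test_dilution_ladder_reproduces_printed_linear_ranges(printed_curves):
    """Stock / 100 .. stock / 1 matches the printed range of every analyte."""
    ranges = reconstruct_linear_ranges()
    for code, curve in printed_curves.items():
        lo, hi = ranges.loc[code]
        assert round(lo, 2) == curve.linear_range[0]
        assert round(hi, 2) == curve.linear_range[1]
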