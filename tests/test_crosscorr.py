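"""Normalized time-lagged cross-correlation: oracle equivalence, bounds,
lag-sign semantics, retention filtering."""

import numpy as np
import pytest

from pocketdyn.crosscorr import (CorrelationEntry, CorrelationError,
                                 CorrelationExtremum, CorrelationReport,
                                 correlation_matrix, cross_correlation,
                                 filter_significant, find_extrema)
from pocketdyn.trajectory import TimeSeries


def ts(values, name="x", dt=0.25):
    return TimeSeries(name=name, values=values, dt=dt)


def brute_force_xcorr(xv, yv, k_max):
    """Independent oracle: explicit double loop over (sample, lag).

    Mean-subtract; numerator averaged over the overlap; denominator from
    the full-series mean squares.
    """
    n = len(xv)
    xc = [v - sum(xv) / n for v in xv]
    yc = [v - sum(yv) / n for v in yv]
    mx2 = sum(v * v for v in xc) / n
    my2 = sum(v * v for v in yc) / n
    denom = (mx2 * my2) ** 0.5
    out = []
    for k in range(-k_max, k_max + 1):
        acc, cnt = 0.0, 0
        for i in range(n):
            j = i + k
            if 0 <= j < n:
                acc += xc[j] * yc[i]
                cnt += 1
        out.append(max(-1.0, min(1.0, (acc / cnt) / denom)))
    return np.array(out)


class TestEstimator:
    def test_self_correlation_is_exactly_one_at_zero_lag(self, rng):
        x = ts(rng.normal(size=500))
        cc = cross_correlation(x, x, max_lag=10 * 0.25)
        assert cc.r[len(cc.r) // 2] == 1.0

    def test_negated_series_gives_minus_one(self, rng):
        xv = rng.normal(size=500)
        cc = cross_correlation(ts(xv, "x"), ts(-xv, "y"), max_lag=2.5)
        assert cc.r[len(cc.r) // 2] == -1.0

    def test_agrees_with_brute_force_oracle(self, rng):
        xv = rng.normal(size=300)
        yv = rng.normal(size=300)
        k_max = 60
        cc = cross_correlation(ts(xv), ts(yv, "y"), max_lag=k_max * 0.25)
        oracle = brute_force_xcorr(xv, yv, k_max)
        assert np.max(np.abs(cc.r - oracle)) <= 1e-10

    @pytest.mark.parametrize("d", [1, 10, 100])
    def test_shifted_copy_peaks_at_minus_d(self, rng, d):
        """y(t) = x(t - d): the global max of r_xy sits at tau = -d dt —
        a negative peak lag means y lags behind x."""
        n = 2000
        base = rng.normal(size=n + d)
        x = ts(base[d:], "x")
        y = ts(base[:n], "y")
        cc = cross_correlation(x, y, max_lag=300 * 0.25)
        assert cc.lags[np.argmax(cc.r)] == pytest.approx(-d * 0.25)

    def test_bounds_and_overlap_bookkeeping(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 400))
            cc = cross_correlation(ts(rng.normal(size=n)),
                                   ts(rng.normal(size=n), "y"))
            assert np.all(np.abs(cc.r) <= 1.0 + 1e-12)
            k = np.rint(cc.lags / cc.dt).astype(int)
            np.testing.assert_array_equal(cc.overlap, n - np.abs(k))
            np.testing.assert_array_equal(cc.lags, -cc.lags[::-1])

    def test_argument_swap_antisymmetry_is_bit_exact(self, rng):
        x = ts(rng.normal(size=400), "x")
        y = ts(rng.normal(size=400), "y")
        fwd = cross_correlation(x, y, max_lag=50.0)
        rev = cross_correlation(y, x, max_lag=50.0)
        np.testing.assert_array_equal(fwd.r, rev.r[::-1])

    def test_linear_invariance(self, rng):
        xv = rng.normal(size=300)
        yv = rng.normal(size=300)
        base = cross_correlation(ts(xv), ts(yv, "y"), max_lag=25.0)
        scaled = cross_correlation(ts(3.2 * xv + 7.0), ts(yv, "y"),
                                   max_lag=25.0)
        np.testing.assert_allclose(scaled.r, base.r, atol=1e-12)
        negated = cross_correlation(ts(-3.2 * xv + 7.0), ts(yv, "y"),
                                    max_lag=25.0)
        np.testing.assert_allclose(negated.r, -base.r, atol=1e-12)

    def test_input_validation(self, rng):
        x = ts(rng.normal(size=100))
        with pytest.raises(CorrelationError, match="constant"):
            cross_correlation(x, ts(np.full(100, 2.0), "const"))
        with pytest.raises(CorrelationError, match="dt"):
            cross_correlation(x, ts(rng.normal(size=100), dt=0.5))
        with pytest.raises(CorrelationError, match="max_lag"):
            cross_correlation(x, ts(rng.normal(size=100), "y"),
                              max_lag=99 * 0.25)

    def test_low_overlap_warns(self, rng):
        x = ts(rng.normal(size=40), "x")
        y = ts(rng.normal(size=40), "y")
        with pytest.warns(UserWarning, match="overlap"):
            cross_correlation(x, y)


class TestExtrema:
    def test_cosine_yields_symmetric_extrema(self):
        # r(tau) = 0.6 cos(2 pi tau / P) on a grid covering one period:
        # max 0.6 at tau = 0, minima -0.6 at tau = +-P/2
        dt = 0.25
        period = 100 * dt
        t = dt * np.arange(-60, 61)
        r = 0.6 * np.cos(2 * np.pi * t / period)
        from pocketdyn.crosscorr import CrossCorrelation
        cc = CrossCorrelation(x_name="x", y_name="y", lags=t, r=r,
                              overlap=np.full(t.size, 1000), dt=dt)
        ext = find_extrema(cc, min_separation=5 * dt)
        maxima = [e for e in ext if e.sign == "max"]
        minima = sorted(e.lag for e in ext if e.sign == "min")
        assert len(maxima) == 1
        assert maxima[0].r_value == pytest.approx(0.6)
        assert maxima[0].lag == pytest.approx(0.0)
        assert minima == [-period / 2, period / 2]
        assert all(e.r_value == pytest.approx(-0.6)
                   for e in ext if e.sign == "min")

    def test_monotone_r_returns_empty(self):
        from pocketdyn.crosscorr import CrossCorrelation
        t = 0.25 * np.arange(-50, 51)
        cc = CrossCorrelation(x_name="x", y_name="y", lags=t,
                              r=np.linspace(-0.9, 0.9, t.size),
                              overlap=np.full(t.size, 100), dt=0.25)
        assert find_extrema(cc, min_separation=1.0) == []

    def test_global_extremum_reported_first_even_below_threshold(self):
        from pocketdyn.crosscorr import CrossCorrelation
        t = 0.25 * np.arange(-50, 51)
        r = 0.3 * np.exp(-((t - 2.0) ** 2) / 10.0)
        cc = CrossCorrelation(x_name="x", y_name="y", lags=t, r=r,
                              overlap=np.full(t.size, 100), dt=0.25)
        ext = find_extrema(cc, min_separation=1.0, threshold=0.45)
        assert len(ext) == 1
        assert ext[0].r_value == pytest.approx(0.3, abs=0.01)


class TestRetention:
    def _report(self, r_values):
        extrema = tuple(CorrelationExtremum(r, 10.0 * i, "max")
                        for i, r in enumerate(r_values))
        entry = CorrelationEntry(pair=("a", "b"), extrema=extrema,
                                 retained=False)
        return CorrelationReport(entries=(entry,))

    def test_strictly_above_threshold_retained(self):
        rep = filter_significant(self._report([0.53, 0.30, -0.66]))
        assert rep.entries[0].retained

    def test_exactly_at_threshold_not_retained(self):
        rep = filter_significant(self._report([0.45, -0.45]))
        assert not rep.entries[0].retained

    def test_empty_extrema_not_retained(self):
        rep = filter_significant(self._report([]))
        assert not rep.entries[0].retained

    def test_threshold_validation(self):
        with pytest.raises(CorrelationError):
            filter_significant(self._report([0.5]), threshold=1.5)


class TestCorrelationMatrix:
    def test_one_entry_per_requested_pair(self, rng):
        series = [ts(rng.normal(size=400), f"hb{i}") for i in range(3)]
        series.append(ts(rng.normal(size=400), "cavity_volume"))
        pairs = [(f"hb{i}", "cavity_volume") for i in range(3)]
        rep = correlation_matrix(series, pairs, max_lag=25.0)
        assert [e.pair for e in rep.entries] == pairs

    def test_self_pair_flagged(self, rng):
        x = ts(rng.normal(size=200), "x")
        rep = correlation_matrix([x], [("x", "x")], max_lag=10.0)
        assert rep.entries[0].self_pair
        assert rep.entries[0].extrema[0].r_value == pytest.approx(1.0)

    def test_unknown_series_name_errors(self, rng):
        x = ts(rng.normal(size=200), "x")
        with pytest.raises(CorrelationError, match="ghost"):
            correlation_matrix([x], [("x", "ghost")], max_lag=10.0)

    def test_format_table_lists_value_and_delay(self, rng):
        n = 4000
        base = rng.normal(size=n + 20)
        x = ts(base[20:], "O(Tyr66)-O(Wat)")
        y = ts(base[:n], "cavity_volume")
        rep = correlation_matrix([x, y],
                                 [("O(Tyr66)-O(Wat)", "cavity_volume")],
                                 max_lag=50.0)
        table = rep.format_table()
        assert "O(Tyr66)-O(Wat) / cavity_volume" in table
        assert "(-5)" in table  # peak at tau = -20 * 0.25 fs
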