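"""Dose-response binning, the ratio-of-variances statistic and regime
threshold detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import gmean

import cytodose as cd
from cytodose.regimes import (assign_regimes, build_drc, detect_thresholds,
                              global_thresholds, rov_series, Candidate)


def _records(expr, values, name="d"):
    return pd.DataFrame({"total_gfp": expr, name: values})


def make_population(seed, t1=3.5, t2=5.0, baseline=100.0, plateau=1000.0,
                    n=4000, cv=0.05):
    """Cells with log-uniform expression and one noisy transfer function."""
    rng = np.random.default_rng(seed)
    expr = 10.0 ** rng.uniform(2, 6, n)
    tf = cd.TransferFunction(baseline, t1, t2, plateau, noise_cv=cv)
    sigma = np.sqrt(np.log(1 + cv ** 2)) if cv > 0 else 0.0
    vals = tf.value(expr) * np.exp(rng.normal(0.0, sigma, n))
    return _records(expr, vals)


class TestBuildDrc:
    def test_geometric_pooling_example(self):
        # two bins of two: gmean(1,100)=10, gmean(9,16)=12
        df = _records([1.0, 2.0, 3.0, 4.0], [1.0, 100.0, 9.0, 16.0])
        curve = build_drc(df, "d", n_min=2, pooling="gmean")
        np.testing.assert_allclose(curve.stat, [10.0, 12.0], rtol=1e-10)

    def test_median_pooling(self):
        df = _records(np.arange(1.0, 7.0), [1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        curve = build_drc(df, "d", n_min=3, pooling="median")
        np.testing.assert_allclose(curve.stat, [2.0, 8.0])

    def test_too_few_records_names_shortfall(self):
        df = _records([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="short"):
            build_drc(df, "d", n_min=100)

    def test_bins_ordered_and_large_enough(self, rng):
        df = _records(rng.lognormal(3, 1, 523), rng.uniform(1, 2, 523))
        curve = build_drc(df, "d", n_min=50)
        assert np.all(np.diff(curve.expression) > 0)
        assert np.all(curve.n >= 50)
        assert curve.n.sum() == 523

    def test_flat_population_within_dispersion(self):
        df = make_population(0, baseline=100.0, plateau=100.0, n=1000,
                             cv=0.05)
        curve = build_drc(df, "d", n_min=100, pooling="gmean")
        # every bin statistic within 3 geometric SDs of the baseline
        gsd = np.exp(np.sqrt(np.log(1 + 0.05 ** 2)))
        assert np.all(curve.stat < 100.0 * gsd ** 3)
        assert np.all(curve.stat > 100.0 / gsd ** 3)

    def test_gmean_scaling_equivariance(self):
        df = make_population(1, n=1000)
        c1 = build_drc(df, "d", n_min=100)
        df2 = df.assign(d=df["d"] * 7.5)
        c2 = build_drc(df2, "d", n_min=100)
        np.testing.assert_allclose(c2.stat, 7.5 * c1.stat, rtol=1e-10)
        r1 = rov_series(c1.stat, N=3, log=True)
        r2 = rov_series(c2.stat, N=3, log=True)
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-9,
                                   equal_nan=True)


def brute_force_rov(d, N, log=True):
    x = np.log(np.asarray(d, float)) if log else np.asarray(d, float)
    out = np.full(len(x), np.nan)
    for i in range(len(x)):
        lead = x[i + 1:i + N + 1]
        trail = x[i - N:i] if i - N >= 0 else x[0:0]
        if len(lead) < N or len(trail) < N:
            continue
        mt = trail.mean()
        vt = ((trail - mt) ** 2).sum() / (N - 1)
        ml = lead.mean()
        vl = ((lead - ml) ** 2).sum() / (N - 1)
        if vt == 0:
            continue
        out[i] = vl / vt
    return out


class TestRovSeries:
    def test_hand_evaluated_example(self):
        # d = (1,2,3,10,20,30), N=2, point 3 (1-based):
        # var(10,20)/var(1,2) = 50/0.5 = 100 on the raw scale
        rov = rov_series([1, 2, 3, 10, 20, 30], N=2, log=False)
        assert rov.values[2] == pytest.approx(100.0, rel=1e-12)

    def test_symmetric_windows_give_one(self):
        d = [5.0, 7.0, 9.0, 1.0, 5.0, 7.0, 9.0]
        rov = rov_series(d, N=3, log=False)
        assert rov.values[3] == pytest.approx(1.0, rel=1e-12)

    def test_constant_trailing_window_flagged(self):
        d = [2.0, 2.0, 2.0, 5.0, 6.0, 9.0, 4.0]
        rov = rov_series(d, N=3, log=False)
        assert np.isnan(rov.values[3])
        assert not np.isinf(rov.values[np.isfinite(rov.values)]).any()

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="short"):
            rov_series([1.0, 2.0, 3.0], N=2)
        with pytest.raises(ValueError):
            rov_series(np.ones(10), N=1)

    def test_log_scale_requires_positive(self):
        with pytest.raises(ValueError):
            rov_series([1.0, -1.0, 1.0, 1.0, 1.0], N=2, log=True)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(7, 60)
            N = int(rng.integers(2, min(5, (n - 1) // 2) + 1))
            d = rng.lognormal(0, 1, n)
            mine = rov_series(d, N=N, log=True).values
            oracle = brute_force_rov(d, N, log=True)
            np.testing.assert_allclose(mine, oracle, rtol=1e-12,
                                       equal_nan=True)

    def test_reversal_antisymmetry(self, rng):
        # reversing the series swaps leading and trailing windows:
        # RoV_i(reversed) = 1 / RoV_{n-1-i}(original)
        d = rng.lognormal(0, 1, 41)
        fwd = rov_series(d, N=4, log=True).values
        rev = rov_series(d[::-1], N=4, log=True).values
        n = len(d)
        for i in range(n):
            j = n - 1 - i
            if np.isfinite(fwd[i]) and np.isfinite(rev[j]):
                assert rev[j] == pytest.approx(1.0 / fwd[i], rel=1e-9)


class TestDetectThresholds:
    def test_noise_free_log_linear_curve_has_no_candidates(self):
        expr = np.logspace(2, 6, 30)
        d = expr ** 0.5
        rov = rov_series(d, N=3, log=True)
        assert detect_thresholds(rov) == []

    def test_two_breakpoints_recovered(self):
        hits = 0
        for seed in range(20):
            df = make_population(seed)
            curve = build_drc(df, "d", n_min=100)
            rov = rov_series(curve.stat, N=3)
            cands = detect_thresholds(rov, curve)
            lx = np.log10(curve.expression)
            i1, i2 = np.argmin(abs(lx - 3.5)), np.argmin(abs(lx - 5.0))
            ups = [c.index for c in cands if c.direction == "up"]
            downs = [c.index for c in cands if c.direction == "down"]
            if (len(cands) == 2 and ups and downs
                    and abs(ups[0] - i1) <= 2 and abs(downs[0] - i2) <= 2):
                hits += 1
        assert hits >= 18

    def test_single_breakpoint_yields_one_up_candidate(self):
        # baseline then unbounded log-linear rise: one transition only
        rng = np.random.default_rng(5)
        expr = 10.0 ** rng.uniform(2, 6, 4000)
        vals = np.where(expr < 10 ** 4, 100.0,
                        100.0 * (expr / 10 ** 4) ** 0.75)
        vals = vals * np.exp(rng.normal(0, 0.05, len(expr)))
        curve = build_drc(_records(expr, vals), "d", n_min=100)
        cands = detect_thresholds(rov_series(curve.stat, N=3), curve)
        assert len(cands) == 1
        assert cands[0].direction == "up"
        assert abs(np.log10(cands[0].expression) - 4.0) < 0.3

    def test_null_population_mostly_clean(self):
        clean = 0
        for seed in range(20):
            df = make_population(seed, baseline=100.0, plateau=100.0)
            curve = build_drc(df, "d", n_min=100)
            cands = detect_thresholds(rov_series(curve.stat, N=3), curve)
            clean += (len(cands) == 0)
        assert clean >= 18


class TestGlobalThresholds:
    def _cand(self, expr, direction):
        return Candidate(expression=expr, index=0, direction=direction,
                         magnitude=3.0)

    def test_single_curve_identity(self):
        g1, g2 = global_thresholds(
            [[self._cand(1e3, "up"), self._cand(1e5, "down")]])
        assert g1 == pytest.approx(1e3)
        assert g2 == pytest.approx(1e5)

    def test_geometric_mean_of_lowers(self):
        g1, g2 = global_thresholds([
            [self._cand(1e2, "up"), self._cand(1e6, "down")],
            [self._cand(1e4, "up")],
        ])
        assert g1 == pytest.approx(1e3)

    def test_missing_side_raises(self):
        with pytest.raises(ValueError, match="candidate"):
            global_thresholds([[self._cand(1e3, "up")]])

    def test_crossed_thresholds_raise(self):
        with pytest.raises(ValueError, match="crossed"):
            global_thresholds(
                [[self._cand(1e5, "up"), self._cand(1e3, "down")]])


class TestAssignRegimes:
    def test_boundary_conventions(self):
        df = _records([10.0, 100.0, 1000.0], [1, 1, 1])
        seg = assign_regimes(df, g1=100.0, g2=1000.0)
        assert list(seg.labels) == ["no_effect", "dose_response",
                                    "saturation"]

    def test_all_below_g1(self):
        df = _records(np.linspace(1, 9, 20), np.ones(20))
        seg = assign_regimes(df, g1=100.0, g2=1000.0)
        assert seg.counts["no_effect"] == 20
        assert sum(seg.counts.values()) == 20

    def test_invalid_thresholds(self):
        df = _records([1.0], [1.0])
        with pytest.raises(ValueError):
            assign_regimes(df, g1=10.0, g2=10.0)

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e9),
                    min_size=1, max_size=50))
    def test_counts_partition_population(self, exprs):
        df = _records(exprs, np.ones(len(exprs)))
        seg = assign_regimes(df, g1=10.0, g2=1e4)
        assert sum(seg.counts.values()) == len(exprs)
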