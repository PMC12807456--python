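import math

import numpy as np
import pytest

import oracles
from glucotriad import (GlucoseTrace, ac_metrics, acf, adrr, bgri, conga,
                        grade, index_panel, jindex, li, mag, mage, modd,
                        mvalue, summary_stats)
from glucotriad.indices import IndexError_, lags_for_interval
from glucotriad.trace import MGDL_PER_MMOL

from conftest import make_random_trace


def constant_trace(value=100.0, days=1, interval=5.0):
    n = int(days * 1440 / interval)
    return GlucoseTrace("c", np.arange(n) * interval, np.full(n, value),
                        sampling_interval=interval)


class TestAcf:
    def test_constant_trace_errors(self):
        with pytest.raises(IndexError_, match="undefined"):
            acf(constant_trace(), K=30)

    def test_ar1_lag1_matches_theory(self):
        rng = np.random.default_rng(0)
        phi, n = 0.8, 5000
        x = np.empty(n)
        x[0] = rng.normal(0, 1 / np.sqrt(1 - phi ** 2))
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        tr = GlucoseTrace("ar", np.arange(n) * 5.0, 150 + 10 * x)
        assert acf(tr, 1).r[0] == pytest.approx(phi, abs=0.03)

    def test_affine_invariance(self, random_traces):
        rng = np.random.default_rng(99)
        for tr in random_traces[:5]:
            base = acf(tr, 10).r
            for _ in range(3):
                a, b = rng.uniform(0.5, 3.0), rng.uniform(0, 50)
                scaled = GlucoseTrace(tr.subject_id, tr.times,
                                      a * tr.values + b, tr.sampling_interval)
                np.testing.assert_allclose(acf(scaled, 10).r, base, atol=1e-10)

    def test_sign_flip_invariance(self, rng):
        # correlation is invariant under g -> -g + c as well
        tr = make_random_trace(rng, days=1)
        flipped = GlucoseTrace("f", tr.times, 500.0 - tr.values,
                               tr.sampling_interval)
        np.testing.assert_allclose(acf(flipped, 10).r, acf(tr, 10).r, atol=1e-10)


class TestAcMetrics:
    def test_equal_lags_zero_variance(self):
        from glucotriad import ACF
        a = ACF(np.arange(1, 11), np.full(10, 0.4))
        m, v = ac_metrics(a)
        assert m == pytest.approx(0.4) and v == pytest.approx(0.0)

    def test_geometric_sequence_oracle(self):
        # exact AR(1) ACF phi^k: mean/variance have closed forms
        phi, K = 0.9, 30
        from glucotriad import ACF
        r = phi ** np.arange(1, K + 1)
        m, v = ac_metrics(ACF(np.arange(1, K + 1), r))
        assert m == pytest.approx(r.mean(), rel=1e-12)
        assert v == pytest.approx(r.var(ddof=1), rel=1e-12)

    def test_lag_window_follows_sampling(self):
        assert lags_for_interval(5.0) == 30
        assert lags_for_interval(15.0) == 10


class TestSummary:
    def test_constant(self):
        m, s, t = summary_stats(constant_trace(100.0))
        assert (m, s, t) == (100.0, 0.0, 100.0)

    def test_tir_half_in_range(self):
        tr = GlucoseTrace("a", [0, 5, 10, 15], [65, 100, 185, 170])
        assert summary_stats(tr)[2] == pytest.approx(50.0)

    def test_permutation_invariance(self, rng):
        tr = make_random_trace(rng, days=1)
        perm = rng.permutation(len(tr))
        tr2 = GlucoseTrace("p", tr.times, tr.values[perm], tr.sampling_interval)
        assert summary_stats(tr2) == pytest.approx(summary_stats(tr))


class TestConga:
    def test_constant_zero(self):
        assert conga(constant_trace()) == pytest.approx(0.0)

    def test_alternating_hourly(self):
        g_mmol = np.array([5.0, 6.0] * 6)[:11]
        tr = GlucoseTrace("a", np.arange(11) * 60.0, g_mmol * MGDL_PER_MMOL,
                          sampling_interval=60.0)
        # differences alternate +-1 over 10 values; Std = sqrt(10/9)
        assert conga(tr, 1.0) == pytest.approx(math.sqrt(10 / 9), rel=1e-9)

    def test_offset_invariance(self, rng):
        tr = make_random_trace(rng, days=1)
        tr2 = GlucoseTrace("o", tr.times, tr.values + 30, tr.sampling_interval)
        assert conga(tr2) == pytest.approx(conga(tr), rel=1e-12)

    def test_short_span_errors(self):
        tr = GlucoseTrace("a", [0, 5, 10], [100, 110, 105], sampling_interval=5)
        with pytest.raises(IndexError_):
            conga(tr, 1.0)


class TestLi:
    def test_hand_example(self):
        g = np.array([5.0, 7.0, 5.0]) * MGDL_PER_MMOL
        tr = GlucoseTrace("a", [0.0, 60.0, 120.0], g, sampling_interval=60)
        assert li(tr) == pytest.approx(4.0, rel=1e-9)

    def test_constant_zero(self):
        assert li(constant_trace()) == pytest.approx(0.0)

    def test_quadratic_scaling(self):
        base = np.array([5.0, 6.0, 5.0, 6.0]) * MGDL_PER_MMOL
        doubled = np.array([5.0, 7.0, 5.0, 7.0]) * MGDL_PER_MMOL
        t = np.arange(4) * 60.0
        a = li(GlucoseTrace("a", t, base, 60))
        b = li(GlucoseTrace("b", t, doubled, 60))
        assert b == pytest.approx(4 * a, rel=1e-9)


class TestJindex:
    def test_unit_converted_formula(self):
        rng = np.random.default_rng(3)
        g = rng.normal(100, 20, size=500)
        tr = GlucoseTrace("a", np.arange(500) * 5.0, np.abs(g) + 1)
        m, s, _ = summary_stats(tr)
        assert jindex(tr) == pytest.approx(0.324 * ((m + s) / MGDL_PER_MMOL) ** 2)

    def test_constant(self):
        assert jindex(constant_trace(90.08)) == pytest.approx(0.324 * 5.0 ** 2)

    def test_monotone_in_std(self):
        t = np.arange(100) * 5.0
        narrow = GlucoseTrace("n", t, 100 + 5 * np.sin(t / 50))
        wide = GlucoseTrace("w", t, 100 + 20 * np.sin(t / 50))
        assert jindex(wide) > jindex(narrow)


class TestBgri:
    # analytic root of f(g) = 1.509((ln g)^1.084 - 5.381)
    G_ROOT = math.exp(5.381 ** (1 / 1.084))

    def test_near_root_both_indices_vanish(self):
        h, l, _, _ = bgri(constant_trace(self.G_ROOT))
        assert h == pytest.approx(0.0, abs=1e-10)
        assert l == pytest.approx(0.0, abs=1e-10)

    def test_hyperglycemia_one_sided(self):
        h, l, rl, rh = bgri(constant_trace(300.0))
        f = 1.509 * (math.log(300.0) ** 1.084 - 5.381)
        assert l == 0.0 and h == pytest.approx(10 * f ** 2)

    def test_partition_identity(self, rng):
        tr = make_random_trace(rng, days=1, mu=110)
        h, l, rl, rh = bgri(tr)
        f = 1.509 * (np.log(tr.values) ** 1.084 - 5.381)
        assert h + l == pytest.approx(np.mean(10 * f ** 2))


class TestGrade:
    G_ROOT_MMOL = 10 ** (10 ** -0.16)  # score root, approx 4.92 mmol/L

    def test_analytic_root(self):
        tr = constant_trace(self.G_ROOT_MMOL * MGDL_PER_MMOL)
        assert grade(tr) == pytest.approx(0.0, abs=1e-10)

    def test_extreme_reading_capped(self):
        assert grade(constant_trace(700.0)) == pytest.approx(50.0)

    def test_mean_of_per_reading_scores(self, rng):
        tr = make_random_trace(rng, days=1)
        scores = np.minimum(
            425 * (np.log10(np.log10(tr.values / MGDL_PER_MMOL)) + 0.16) ** 2, 50.0)
        assert grade(tr) == pytest.approx(scores.mean())


class TestModd:
    def test_identical_days_zero(self, rng):
        day = make_random_trace(rng, days=1, interval=5.0)
        t = np.concatenate([day.times, day.times + 1440])
        g = np.concatenate([day.values, day.values])
        assert modd(GlucoseTrace("a", t, g, 5.0)) == pytest.approx(0.0)

    def test_constant_offset_one_mmol(self, rng):
        day = make_random_trace(rng, days=1, interval=5.0)
        t = np.concatenate([day.times, day.times + 1440])
        g = np.concatenate([day.values, day.values + MGDL_PER_MMOL])
        assert modd(GlucoseTrace("a", t, g, 5.0)) == pytest.approx(1.0)

    def test_three_day_brute_force(self, rng):
        tr = make_random_trace(rng, days=3, interval=15.0)
        assert modd(tr) == pytest.approx(oracles.naive_modd(tr), rel=1e-10)

    def test_single_day_errors(self, rng):
        with pytest.raises(IndexError_):
            modd(make_random_trace(rng, days=1))


class TestMage:
    def test_constant_flagged_zero(self):
        val, flagged = mage(constant_trace())
        assert val == 0.0 and flagged

    def test_sinusoid_amplitude(self):
        t = np.arange(0, 1440, 5.0)
        g = 100 + 20 * np.sin(2 * np.pi * t / 240.0)  # swings of 40 mg/dL
        val, flagged = mage(GlucoseTrace("s", t, g, 5.0))
        assert not flagged
        assert val == pytest.approx(40.0 / MGDL_PER_MMOL, rel=0.01)

    def test_small_noise_robustness(self, rng):
        t = np.arange(0, 1440, 5.0)
        g = 100 + 20 * np.sin(2 * np.pi * t / 240.0)
        clean, _ = mage(GlucoseTrace("s", t, g, 5.0))
        sd = g.std(ddof=1)
        noisy, _ = mage(GlucoseTrace("n", t, g + rng.normal(0, 0.05 * sd, len(t)),
                                     5.0))
        assert noisy == pytest.approx(clean, rel=0.05)


class TestAdrr:
    def test_near_root_constant_tiny(self):
        tr = constant_trace(TestBgri.G_ROOT, days=3)
        assert adrr(tr) == pytest.approx(0.0, abs=1e-10)

    def test_single_spike_day_mean(self):
        t = np.arange(0, 3 * 1440, 5.0)
        g = np.full(len(t), TestBgri.G_ROOT)
        g[30] = 320.0  # one hyperglycemic spike on day 1
        tr = GlucoseTrace("a", t, g, 5.0)
        f = 1.509 * (math.log(320.0) ** 1.084 - 5.381)
        assert adrr(tr) == pytest.approx(10 * f ** 2 / 3, rel=1e-9)

    def test_day_permutation_invariance(self, rng):
        day_vals = [make_random_trace(rng, days=1).values for _ in range(3)]
        t = np.arange(0, 3 * 1440, 5.0)
        a = adrr(GlucoseTrace("a", t, np.concatenate(day_vals), 5.0))
        b = adrr(GlucoseTrace("b", t, np.concatenate(day_vals[::-1]), 5.0))
        assert b == pytest.approx(a, rel=1e-12)


class TestMvalue:
    def test_ideal_constant_zero(self):
        assert mvalue(constant_trace(120.0)) == pytest.approx(0.0)

    def test_double_ideal(self):
        expected = abs(10 * math.log10(2.0)) ** 3
        assert mvalue(constant_trace(240.0)) == pytest.approx(expected)

    def test_range_correction_additive(self):
        tr1 = GlucoseTrace("a", [0, 5, 10, 15], [120, 120, 120, 120.0])
        tr2 = GlucoseTrace("b", [0, 5, 10, 15], [120, 120, 120, 120.0 + 40])
        delta_scores = abs(10 * math.log10(160 / 120)) ** 3 / 4
        assert mvalue(tr2) - mvalue(tr1) == pytest.approx(delta_scores + 40 / 20)


class TestMag:
    def test_monotone_ramp(self):
        g = np.linspace(100, 100 + 5 * MGDL_PER_MMOL, 61)
        tr = GlucoseTrace("r", np.arange(61) * 5.0, g, 5.0)
        assert mag(tr) == pytest.approx(1.0, rel=1e-9)

    def test_constant_zero(self):
        assert mag(constant_trace()) == pytest.approx(0.0)

    def test_time_reversal_invariance(self, rng):
        tr = make_random_trace(rng, days=1)
        rev = GlucoseTrace("r", tr.times, tr.values[::-1], tr.sampling_interval)
        assert mag(rev) == pytest.approx(mag(tr), rel=1e-12)


class TestPanel:
    def test_five_minute_panel_complete(self, rng):
        tr = make_random_trace(rng, days=3, interval=5.0)
        panel, reasons = index_panel(tr)
        assert len(panel) == 15 and not reasons
        m, v = ac_metrics(acf(tr, 30))
        assert panel["AC_Var"] == pytest.approx(v)

    def test_fifteen_minute_uses_ten_lags(self, rng):
        tr = make_random_trace(rng, days=3, interval=15.0)
        panel, _ = index_panel(tr)
        m, v = ac_metrics(acf(tr, 10))
        assert panel["AC_Mean"] == pytest.approx(m)
        assert panel["AC_Var"] == pytest.approx(v)

    def test_one_day_trace_modd_missing(self, rng):
        tr = make_random_trace(rng, days=1, interval=5.0)
        panel, reasons = index_panel(tr)
        assert np.isnan(panel["MODD"]) and "MODD" in reasons
        assert np.isfinite(panel["ADRR"])  # one complete day suffices
        for name in ("CGM_Mean", "MAGE", "AC_Var", "TIR"):
            assert np.isfinite(panel[name])

    def test_short_trace_adrr_missing(self, rng):
        full = make_random_trace(rng, days=1, interval=5.0)
        keep = full.times < 15 * 60  # 15 h of coverage: no complete day
        tr = GlucoseTrace("short", full.times[keep], full.values[keep], 5.0)
        panel, reasons = index_panel(tr)
        assert np.isnan(panel["ADRR"]) and "ADRR" in reasons

    def test_nonnegative_indices(self, random_traces):
        nonneg = ["CGM_Std", "CONGA", "LI", "JINDEX", "HBGI", "GRADE",
                  "MODD", "MAGE", "ADRR", "MVALUE", "MAG"]
        for tr in random_traces:
            panel, _ = index_panel(tr)
            for name in nonneg:
                if np.isfinite(panel[name]):
                    assert panel[name] >= 0, name
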