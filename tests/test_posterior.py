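"""HPDI, the band-significance rule, and dual-scale summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mscmig.inference import McmcSettings, McmcTrace
from mscmig.posterior import (band_significant, hpdi, select_bands,
                              summarize)


def brute_force_hpdi(samples, level):
    """Exhaustive shortest-window search (independent oracle)."""
    x = np.sort(np.asarray(samples, float))
    n = x.size
    k = min(int(np.ceil(level * n)), n)
    best = None
    for j in range(n - k + 1):
        w = x[j + k - 1] - x[j]
        if best is None or w < best[0] - 1e-300:
            best = (w, x[j], x[j + k - 1])
    return best[1], best[2]


class TestHpdi:
    def test_constant_series(self):
        assert hpdi([3.3] * 10) == (3.3, 3.3)

    def test_uniform_grid_tie_break(self):
        # all width-94 windows over 0..99 tie; smallest lower bound wins
        assert hpdi(np.arange(100), 0.95) == (0.0, 94.0)

    def test_narrower_than_equal_tailed_for_exponential(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=5000)
        lo, hi = hpdi(x, 0.95)
        eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
        assert hi - lo < eq_hi - eq_lo
        assert lo < eq_lo  # the HPDI hugs the mode at 0

    def test_empty_and_bad_level(self):
        with pytest.raises(ValueError):
            hpdi([])
        with pytest.raises(ValueError):
            hpdi([1.0, 2.0], 1.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=400),
           st.sampled_from([0.5, 0.8, 0.9, 0.95]))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force(self, xs, level):
        got = hpdi(xs, level)
        want = brute_force_hpdi(xs, level)
        # window width is what is optimised; ties may differ in location
        assert got[1] - got[0] == pytest.approx(want[1] - want[0],
                                                abs=1e-9)
        assert got == pytest.approx(want)

    def test_agrees_with_arviz_width(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        x = rng.gamma(3.0, 2.0, size=20_000)
        lo, hi = hpdi(x, 0.9)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)


class TestBandSignificant:
    def test_all_zero_not_significant(self):
        d = band_significant(np.zeros(500))
        assert not d.significant and d.rule == "none"

    def test_threshold_probability_clause(self):
        x = np.array([0.05] * 60 + [0.01] * 40 + [0.0] * 0)
        x = np.repeat(x, 2)  # 200 samples, 60% above 0.03
        d = band_significant(x)
        assert d.significant
        assert d.rule in ("threshold-probability", "hpdi-excludes-0")
        assert d.prob_above_threshold == pytest.approx(0.6)

    def test_half_zero_half_tiny_not_significant(self):
        x = np.array([0.0] * 100 + [0.001] * 100)
        d = band_significant(x)
        assert not d.significant
        assert d.hpdi_lo <= 1e-12 and d.prob_above_threshold == 0.0

    def test_hpdi_clause(self):
        rng = np.random.default_rng(2)
        x = 0.01 + 0.001 * rng.random(500)  # bounded away from 0
        d = band_significant(x)
        assert d.significant and d.rule == "hpdi-excludes-0"

    def test_needs_enough_samples_and_nonnegative(self):
        with pytest.raises(ValueError):
            band_significant(np.zeros(50))
        with pytest.raises(ValueError):
            band_significant(np.array([-0.01] + [0.0] * 199))

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_mass_above_threshold(self, seed):
        """Raising samples above the threshold never revokes significance."""
        rng = np.random.default_rng(seed)
        x = rng.exponential(0.02, size=300)
        d1 = band_significant(x)
        boosted = x.copy()
        boosted[:100] = np.maximum(boosted[:100], 0.05)
        d2 = band_significant(boosted)
        if d1.significant:
            assert d2.significant

    def test_mean_reading_option(self):
        x = np.array([0.05] * 45 + [0.029] * 155)  # mean > 0.03, P=0.225
        d_prob = band_significant(x, use_mean=False)
        d_mean = band_significant(x, use_mean=True)
        assert d_mean.significant
        assert d_prob.rule != "threshold-probability" or d_prob.significant


def _constant_trace(cols: dict, n=200) -> McmcTrace:
    data = {"iter": np.arange(n)}
    for k, v in cols.items():
        data[k] = np.full(n, v)
    data["logL"] = np.zeros(n)
    return McmcTrace(pd.DataFrame(data), {}, McmcSettings())


class TestSummarize:
    def test_dual_scale_point_conversions(self):
        t = _constant_trace({"tau_ancDW": 3.2e-5, "theta_x": 4e-5})
        df = summarize(t).set_index("parameter")
        row = df.loc["tau_ancDW"]
        assert row["mean_combo_i"] == pytest.approx(36_000)
        assert row["mean_combo_ii"] == pytest.approx(9_600)
        # Ne = theta / (4 mu) = 4e-5 / 1.6e-8
        assert df.loc["theta_x", "mean_combo_i"] == pytest.approx(2500)

    def test_scale_ratio_exact_per_parameter(self):
        rng = np.random.default_rng(8)
        t = _constant_trace({})
        t.samples["tau_a"] = rng.gamma(2, 1e-4, len(t.samples))
        t.samples["theta_b"] = rng.gamma(2, 1e-4, len(t.samples))
        df = summarize(t).set_index("parameter")
        for col in ("mean", "lo", "hi"):
            ci = df.loc["tau_a", f"{col}_combo_i" if col == "mean"
                        else f"{col}_i"]
            cii = df.loc["tau_a", f"{col}_combo_ii" if col == "mean"
                         else f"{col}_ii"]
            assert ci / cii == pytest.approx(3.75, rel=1e-12)
            ci = df.loc["theta_b", f"{col}_combo_i" if col == "mean"
                        else f"{col}_i"]
            cii = df.loc["theta_b", f"{col}_combo_ii" if col == "mean"
                         else f"{col}_ii"]
            assert ci / cii == pytest.approx(2.5, rel=1e-12)

    def test_hpdi_brackets_mean_for_unimodal_trace(self):
        rng = np.random.default_rng(3)
        t = _constant_trace({})
        t.samples["theta_u"] = rng.gamma(20, 1e-5, len(t.samples))
        df = summarize(t).set_index("parameter")
        row = df.loc["theta_u"]
        assert row["hpdi_lo_scaled"] <= row["mean_scaled"] \
            <= row["hpdi_hi_scaled"]


def test_select_bands_empty_candidates_runs_no_mcmc(two_pop_model):
    retained, decisions = select_bands([], two_pop_model, [])
    assert retained == [] and decisions == []
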