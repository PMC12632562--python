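"""Viability normalization, DSS, GR metrics, 4PL fits, and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from splicepharm.doseresponse import (
    DoseResponseCurve,
    anova_tukey,
    compute_dss,
    compute_gr,
    fit_4pl,
    mann_whitney,
    normalize_viability,
    regress_vaf_dss,
)
from splicepharm.simulate import SimConfig, gen_dose_response, hill_curve

CONC = np.array([1e-9, 1e-8, 1e-7, 1e-6, 1e-5])


def _curve(viability, conc=CONC):
    return DoseResponseCurve("s", "d", conc, np.asarray(viability, float),
                             np.ones(len(conc)))


def _table(signals_by_conc, dmso, sample="s1"):
    rows = []
    for c, sigs in signals_by_conc.items():
        for rep, s in enumerate(sigs, 1):
            rows.append((sample, "drug", c, "uM", rep, s, False))
    for w, s in enumerate(dmso, 1):
        rows.append((sample, "drug", 0.0, "uM", w, s, True))
    return pd.DataFrame(rows, columns=["sample_id", "drug", "concentration",
                                       "unit", "replicate", "signal", "is_dmso"])


class TestNormalizeViability:
    def test_identity_when_signal_equals_dmso(self):
        tab = _table({0.001: [100], 0.01: [100], 0.1: [100], 1: [100]},
                     dmso=[100, 100])
        (curve,) = normalize_viability(tab)
        np.testing.assert_allclose(curve.viability, 1.0)
        np.testing.assert_allclose(curve.inhibition, 0.0)

    def test_full_kill_at_top_dose(self):
        tab = _table({0.001: [100], 0.01: [80], 0.1: [40], 1: [0]}, dmso=[100])
        (curve,) = normalize_viability(tab)
        assert curve.viability[-1] == 0.0
        assert curve.inhibition[-1] == 100.0

    def test_replicates_averaged_with_n_recorded(self):
        tab = _table({0.001: [40, 60], 0.01: [40, 60], 0.1: [40, 60],
                      1: [40, 60]}, dmso=[100])
        (curve,) = normalize_viability(tab)
        np.testing.assert_allclose(curve.viability, 0.5)
        assert (curve.n_replicates == 2).all()
        assert curve.viab_rep.size == 8  # replicate-level points retained

    def test_unit_conversion_to_molar(self):
        tab = _table({1: [50], 10: [40], 100: [30], 1000: [20]}, dmso=[100])
        (curve,) = normalize_viability(tab)
        np.testing.assert_allclose(curve.concentrations,
                                   [1e-6, 1e-5, 1e-4, 1e-3])

    def test_missing_or_degenerate_dmso_rejected(self):
        tab = _table({0.001: [1], 0.01: [1], 0.1: [1], 1: [1]}, dmso=[])
        with pytest.raises(ValueError, match="DMSO"):
            normalize_viability(tab)
        tab = _table({0.001: [1], 0.01: [1], 0.1: [1], 1: [1]}, dmso=[0.0])
        with pytest.raises(ValueError, match="DMSO"):
            normalize_viability(tab)

    def test_growth_stimulation_permitted(self):
        tab = _table({0.001: [120], 0.01: [110], 0.1: [90], 1: [50]}, dmso=[100])
        (curve,) = normalize_viability(tab)
        assert curve.viability[0] == pytest.approx(1.2)


class TestDSS:
    def test_zero_inhibition_gives_zero(self):
        res = compute_dss(_curve(np.ones(5)), threshold=10)
        assert res.dss == 0.0

    def test_full_inhibition_gives_hundred(self):
        res = compute_dss(_curve(np.zeros(5)), threshold=10)
        assert res.dss == pytest.approx(100.0)

    def test_linear_ramp_with_zero_threshold_gives_fifty(self):
        # inhibition rising linearly 0 -> 100 over the log range is a
        # triangle of half the box area
        inh = np.linspace(0, 100, 5)
        res = compute_dss(_curve(1 - inh / 100), threshold=0)
        assert res.dss == pytest.approx(50.0)

    def test_threshold_crossing_located_exactly(self):
        # ramp 0 -> 100 with t = 50: area above 50 is a triangle over half
        # the log range: A = 0.5 * 50 * 2; DSS = 100*50/(50*4) = 25
        inh = np.linspace(0, 100, 5)
        res = compute_dss(_curve(1 - inh / 100), threshold=50)
        assert res.dss == pytest.approx(25.0)

    def test_subthreshold_activity_scores_zero(self):
        res = compute_dss(_curve(np.full(5, 0.95)), threshold=10)
        assert res.dss == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_pointwise_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        v1 = rng.uniform(0, 1, size=5)
        v2 = np.clip(v1 - rng.uniform(0, 0.3, size=5), 0, 1)  # more inhibition
        assert (compute_dss(_curve(v2)).dss
                >= compute_dss(_curve(v1)).dss - 1e-12)

    def test_dss_vanishes_as_threshold_approaches_hundred(self):
        curve = _curve(np.linspace(1, 0.0, 5))
        assert compute_dss(curve, threshold=99.9).dss < 0.2

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            compute_dss(_curve([1.0, 0.5, 0.1], conc=CONC[:3]))


class TestGR:
    def test_untreated_limit_is_one(self):
        gr = compute_gr(100, np.full(5, 800.0), 800, CONC)
        np.testing.assert_allclose(gr.gr_values, 1.0)

    def test_cytostasis_is_zero(self):
        gr = compute_gr(100, np.full(5, 100.0), 800, CONC)
        np.testing.assert_allclose(gr.gr_values, 0.0)

    def test_closed_form_half_x0(self):
        gr = compute_gr(100, np.array([50.0]), 400, CONC[:1])
        assert gr.gr_values[0] == pytest.approx(2 ** -0.5 - 1)

    def test_gr_bounded_below_by_minus_one(self):
        gr = compute_gr(100, np.array([1e-6, 1.0, 10.0, 100.0, 800.0]), 800, CONC)
        assert (gr.gr_values > -1).all()

    def test_no_growth_control_rejected(self):
        with pytest.raises(ValueError, match="GR undefined"):
            compute_gr(100, np.full(5, 50.0), 100, CONC)

    def test_gr50_recovery_on_noise_free_curve(self):
        gr_inf, gec50, hill = -0.4, 2e-7, 1.3
        gr_true = gr_inf + (1 - gr_inf) / (1 + (CONC / gec50) ** hill)
        # invert the GR transform to build consistent endpoint counts
        x0, x_ctrl = 100.0, 800.0
        x = x0 * (x_ctrl / x0) ** np.log2(gr_true + 1)
        fit = compute_gr(x0, x, x_ctrl, CONC)
        expected_gr50 = gec50 * ((1 - gr_inf) / (0.5 - gr_inf) - 1) ** (1 / hill)
        assert fit.gr50 == pytest.approx(expected_gr50, rel=0.01)

    def test_gr50_undefined_when_curve_stays_above_half(self):
        gr_true = 0.8 + 0.2 / (1 + (CONC / 1e-7))
        x = 100 * 8 ** np.log2(gr_true + 1)
        fit = compute_gr(100, x, 800, CONC)
        assert fit.gr50 is None


class TestFit4PL:
    def test_noise_free_recovery_within_one_percent(self):
        true = dict(top=1.0, bottom=0.0, ec50=1e-7, hill=1.0)
        viab = hill_curve(CONC, **true)
        fit = fit_4pl(_curve(viab))
        assert not fit.no_response
        assert fit.ec50 == pytest.approx(1e-7, rel=0.01)
        assert fit.ic50_abs == pytest.approx(1e-7, rel=0.01)

    def test_flat_viability_flagged_no_response(self):
        fit = fit_4pl(_curve(np.ones(5)))
        assert fit.no_response and fit.ic50_abs is None

    def test_increasing_viability_flagged_no_response(self):
        fit = fit_4pl(_curve([0.8, 0.9, 1.0, 1.1, 1.2]))
        assert fit.no_response and fit.ic50_abs is None

    def test_noisy_recovery_median_error_bounded(self):
        cfg = SimConfig(noise_sd=0.02, seed=31)
        params = [dict(top=1.0, bottom=0.02, ec50=10 ** rng, hill=1.2)
                  for rng in np.linspace(-8, -6.3, 100)]
        table, truth = gen_dose_response(cfg, params)
        curves = normalize_viability(table)
        errs = []
        for c in curves:
            t = truth.curves[c.sample_id]
            fit = fit_4pl(c)
            errs.append(abs(fit.ec50 - t["ec50"]) / t["ec50"])
        assert np.median(errs) <= 0.05

    def test_ic50_undefined_outside_extended_range(self):
        # shallow partial response never reaching 50% inhibition in range
        viab = hill_curve(CONC, 1.0, 0.45, 1e-4, 0.8)
        fit = fit_4pl(_curve(viab))
        assert fit.ic50_abs is None


class TestMannWhitney:
    def test_exact_enumeration_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_exact_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        u, p = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_exact_close_to_asymptotic_at_six_per_group(self):
        a = [1.0, 2.5, 3.1, 4.7, 5.2, 6.9]
        b = [2.1, 3.3, 4.1, 5.5, 7.2, 8.8]
        _, p_exact = mann_whitney(a, b)
        _, p_asym = mann_whitney(a, b, exact_max_n=0)
        assert abs(p_exact - p_asym) < 0.02


class TestRegression:
    def test_collinear_points_recovered_exactly(self):
        vaf = np.array([10.0, 20, 30, 40])
        slope, intercept, r, p = regress_vaf_dss(vaf, 2 * vaf)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-10)
        assert r == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        slope, _, r, _ = regress_vaf_dss([10, 20, 30, 40], [7, 7, 7, 7])
        assert slope == 0.0 and r == 0.0

    def test_duplicated_x_allowed(self):
        slope, _, r, _ = regress_vaf_dss([10, 10, 30, 30], [1, 2, 3, 5])
        assert abs(r) < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            regress_vaf_dss([1, 2], [1, 2])
        with pytest.raises(ValueError):
            regress_vaf_dss([5, 5, 5], [1, 2, 3])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        f, p, _ = anova_tukey([[1, 1.1], [1, 1.1], [1, 1.1]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_near_identical_pair_not_separated(self):
        f, p, pairwise = anova_tukey([[1, 1.1], [1, 1.1], [10, 11]])
        assert p < 0.05
        row = pairwise[(pairwise["group_a"] == "group1")
                       & (pairwise["group_b"] == "group2")]
        assert float(row["p_adj"].iloc[0]) > 0.5

    def test_two_groups_equal_pooled_t_squared(self):
        g1, g2 = [1.0, 1.3, 0.9, 1.1], [2.0, 2.4, 1.8, 2.2]
        f, p, _ = anova_tukey([g1, g2], log_transform=False)
        t, pt = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t ** 2)
        assert p == pytest.approx(pt)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0], [1.0, 2.0]])
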