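"""Deterministic gain engine: worked examples and structural properties."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import halfsib as h
from halfsib.gain import Strategy

from conftest import MEAN200, MEAN1000


def intensity_oracle(p: float) -> float:
    """Independent truncated-normal oracle: mean of the upper-p tail."""
    z = norm.ppf(1 - p)
    return norm.pdf(z) / p


class TestSelectionIntensity:
    @pytest.mark.parametrize("p", [0.2, 0.1, 0.05, 0.02, 0.01])
    def test_matches_truncated_normal_oracle(self, p):
        assert h.selection_intensity(p) == pytest.approx(intensity_oracle(p),
                                                         rel=1e-12)

    def test_known_values(self):
        assert h.selection_intensity(1.0) == 0.0
        assert h.selection_intensity(0.20) == pytest.approx(1.3998, abs=1e-4)
        assert h.selection_intensity(0.01) == pytest.approx(2.6653, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001, 2.0])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            h.selection_intensity(p)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-4, max_value=0.999))
    def test_positive_and_decreasing(self, p):
        i = h.selection_intensity(p)
        assert i > 0
        assert i > h.selection_intensity(min(1.0, p + 1e-3))


class TestFamilyMeanSd:
    def test_printed_components(self, vc200, vc1000, design200, design1000):
        assert h.family_mean_phenotypic_sd(vc1000, design1000) == pytest.approx(
            249.81, abs=0.01)
        assert h.family_mean_phenotypic_sd(vc200, design200) == pytest.approx(
            212.52, abs=0.01)

    def test_collapses_to_family_sd(self, design200):
        vc = h.VarianceComponents(100.0, 0, 0, 0, 0)
        assert h.family_mean_phenotypic_sd(vc, design200) == pytest.approx(10.0)

    def test_lower_bound(self, vc200, design200):
        assert (h.family_mean_phenotypic_sd(vc200, design200)
                >= math.sqrt(vc200.family))


class TestHeritability:
    def test_printed_values(self, vc200, vc1000, design200, design1000):
        h2_200 = h.heritability_family_mean(vc200, design200)
        h2_1000 = h.heritability_family_mean(vc1000, design1000)
        assert round(h2_1000, 2) == 0.36
        assert round(h2_200, 2) == 0.31
        assert h2_1000 == pytest.approx(0.358, abs=0.005)
        assert h2_200 == pytest.approx(0.314, abs=0.005)

    def test_limits(self, design200):
        assert h.heritability_family_mean(
            h.VarianceComponents(5.0, 0, 0, 0, 0), design200
        ) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(ValueError):
            h.heritability_family_mean(
                h.VarianceComponents(0, 0, 0, 0, 0), design200)


class TestAmongFamilyGain:
    def test_printed_20pct(self, vc200, design200):
        g = h.gain_among_phenotypic(vc200, design200, 0.20)
        assert g == pytest.approx(46.67, abs=0.05)
        assert 100 * g / MEAN200 == pytest.approx(1.43, abs=0.02)

    def test_printed_2pct(self, vc200, design200):
        g = h.gain_among_phenotypic(vc200, design200, 0.02)
        assert 100 * g / MEAN200 == pytest.approx(2.47, abs=0.02)

    def test_no_truncation_no_gain(self, vc200, design200):
        assert h.gain_among_phenotypic(vc200, design200, 1.0) == 0.0


class TestWithinFamilyGain:
    def test_printed_values(self, vc200):
        assert h.gain_within_gs(vc200, 0.01, 0.46) == pytest.approx(126.4, abs=0.1)
        assert h.gain_within_gs(vc200, 0.10, 0.26) == pytest.approx(47.0, abs=0.1)

    def test_zero_accuracy(self, vc200):
        assert h.gain_within_gs(vc200, 0.01, 0.0) == 0.0

    def test_linear_in_accuracy(self, vc200):
        g1 = h.gain_within_gs(vc200, 0.05, 0.2)
        g2 = h.gain_within_gs(vc200, 0.05, 0.4)
        assert g2 == pytest.approx(2 * g1)


class TestCombinedStrategies:
    def test_ApWgs_abstract_values(self, vc200, vc1000, design200, design1000):
        scheme = h.SelectionScheme(strategy="A_pWgs", p_among=0.02,
                                   p_within=0.01, r_accuracy=0.46)
        r200 = h.predict_gain(vc200, design200, scheme, MEAN200)
        r1000 = h.predict_gain(vc1000, design1000, scheme, MEAN1000)
        assert r200.delta_g_pct == pytest.approx(6.35, abs=0.02)
        assert r1000.delta_g_pct == pytest.approx(8.10, abs=0.02)

    def test_ApWgs_reduces_to_among_when_accuracy_zero(self, vc200, design200):
        scheme = h.SelectionScheme(strategy="A_pWgs", p_among=0.1,
                                   p_within=0.05, r_accuracy=0.0)
        r = h.predict_gain(vc200, design200, scheme, MEAN200)
        assert r.delta_g_abs == pytest.approx(
            h.gain_among_phenotypic(vc200, design200, 0.1))

    def test_ApWgs_requires_p_within(self):
        with pytest.raises(ValueError):
            h.SelectionScheme(strategy="A_pWgs", p_among=0.1, r_accuracy=0.3)

    def test_AgsWgs_cycle2_values(self, vc200, vc1000, design200, design1000):
        s = h.SelectionScheme(strategy="A_gsWgs", p_among=0.10, p_within=0.05,
                              r_accuracy=0.46, cycle_years=1)
        r = h.predict_gain(vc200, design200, s, 3419.0)
        assert r.delta_g_abs == pytest.approx(145.9, abs=0.1)
        assert r.delta_g_pct == pytest.approx(4.27, abs=0.02)
        s26 = h.SelectionScheme(strategy="A_gsWgs", p_among=0.10, p_within=0.05,
                                r_accuracy=0.26, cycle_years=1)
        r1000 = h.predict_gain(vc1000, design1000, s26, 3449.0)
        assert r1000.delta_g_pct == pytest.approx(3.00, abs=0.02)

    def test_AgsWgs_zero_accuracy_zero_gain(self, vc200, design200):
        s = h.SelectionScheme(strategy="A_gsWgs", p_among=0.10, p_within=0.05,
                              r_accuracy=0.0, cycle_years=1)
        assert h.predict_gain(vc200, design200, s, MEAN200).delta_g_pct == 0.0


class TestPhenomics:
    def test_scales_percent_gain(self, vc200, design200):
        base = h.predict_gain(vc200, design200,
                              h.SelectionScheme(strategy="A_p", p_among=0.2),
                              MEAN200)
        scaled = h.apply_phenomics(base, 0.90)
        assert scaled.delta_g_pct == pytest.approx(1.29, abs=0.02)

    def test_table3_absolute_value(self, vc200, design200):
        scheme = h.SelectionScheme(strategy="A_PhWgs", p_among=0.02,
                                   p_within=0.01, r_accuracy=0.46)
        r = h.predict_gain(vc200, design200, scheme, MEAN200)
        assert r.delta_g_abs == pytest.approx(186.4, abs=0.2)

    def test_identity_accuracy(self, vc200, design200):
        base = h.predict_gain(vc200, design200,
                              h.SelectionScheme(strategy="A_p", p_among=0.2),
                              MEAN200)
        assert h.apply_phenomics(base, 1.0).delta_g_abs == base.delta_g_abs

    @pytest.mark.parametrize("p", [0.2, 0.1, 0.05, 0.02])
    def test_exact_ratio_at_every_pressure(self, vc200, design200, p):
        ap = h.predict_gain(vc200, design200,
                            h.SelectionScheme(strategy="A_p", p_among=p),
                            MEAN200)
        aph = h.predict_gain(vc200, design200,
                             h.SelectionScheme(strategy="A_Ph", p_among=p,
                                               ph_accuracy=0.9), MEAN200)
        assert aph.delta_g_abs / ap.delta_g_abs == pytest.approx(0.9)


class TestCycleChaining:
    def test_progeny_mean_follows(self):
        c1 = h.GainResult(delta_g_abs=93.95, base_mean=MEAN200, cycle_years=3)
        assert c1.next_base_mean == pytest.approx(3356, abs=0.5)

    def test_total_percent_sums(self):
        c1 = h.GainResult(delta_g_abs=93.95, base_mean=MEAN200, cycle_years=3)
        c2 = h.GainResult(delta_g_abs=68.84, base_mean=3356.0, cycle_years=1)
        chain = h.chain_cycles([c1, c2], costs=[100.0, 50.0])
        assert chain.total_pct == pytest.approx(2.88 + 2.05, abs=0.02)
        assert chain.total_pct == pytest.approx(4.93, abs=0.02)
        assert chain.total_cost == 150.0

    def test_single_cycle(self):
        c = h.GainResult(delta_g_abs=50.0, base_mean=1000.0)
        chain = h.chain_cycles([c])
        assert chain.total_pct == c.delta_g_pct
        assert chain.base_means == (1000.0, 1050.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            h.chain_cycles([])
        c1 = h.GainResult(delta_g_abs=50.0, base_mean=1000.0)
        bad = h.GainResult(delta_g_abs=10.0, base_mean=1200.0)
        with pytest.raises(ValueError):
            h.chain_cycles([c1, bad])


class TestParentCounts:
    @pytest.mark.parametrize("p,expected", [(0.20, 40), (0.10, 20),
                                            (0.05, 10), (0.02, 4)])
    def test_among_only_200(self, p, expected):
        assert h.parents_count(200, p) == expected

    @pytest.mark.parametrize("pa,pw,expected", [
        (0.20, 0.10, 400), (0.10, 0.05, 100), (0.05, 0.01, 10), (0.02, 0.01, 4)])
    def test_with_within_gs_200(self, pa, pw, expected):
        assert h.parents_count(200, pa, 100, pw) == expected

    @pytest.mark.parametrize("pa,pw,expected", [
        (0.20, 0.10, 2000), (0.10, 0.05, 500), (0.05, 0.01, 50), (0.02, 0.01, 20)])
    def test_with_within_gs_1000(self, pa, pw, expected):
        assert h.parents_count(1000, pa, 100, pw) == expected

    def test_zero_selected_raises(self):
        with pytest.raises(ValueError):
            h.parents_count(10, 0.01)


class TestMonotonicityAndOrdering:
    @settings(derandomize=True, max_examples=40)
    @given(p=st.floats(min_value=0.02, max_value=0.5),
           r=st.floats(min_value=0.05, max_value=0.95))
    def test_gain_increases_with_pressure_and_accuracy(self, vc200, design200, p, r):
        s_lo = h.SelectionScheme(strategy="A_pWgs", p_among=p, p_within=p / 2,
                                 r_accuracy=r)
        s_hi = h.SelectionScheme(strategy="A_pWgs", p_among=p / 2,
                                 p_within=p / 4, r_accuracy=r)
        g_lo = h.predict_gain(vc200, design200, s_lo, MEAN200).delta_g_abs
        g_hi = h.predict_gain(vc200, design200, s_hi, MEAN200).delta_g_abs
        assert g_hi > g_lo
        s_racc = h.SelectionScheme(strategy="A_pWgs", p_among=p, p_within=p / 2,
                                   r_accuracy=min(1.0, r + 0.04))
        assert (h.predict_gain(vc200, design200, s_racc, MEAN200).delta_g_abs
                > g_lo)

    @pytest.mark.parametrize("pa,pw", [(0.20, 0.10), (0.10, 0.05),
                                       (0.05, 0.01), (0.02, 0.01)])
    @pytest.mark.parametrize("r", [0.26, 0.36, 0.46])
    def test_strategy_ordering(self, vc200, design200, pa, pw, r):
        among = h.gain_among_phenotypic(vc200, design200, pa)
        combined = h.predict_gain(
            vc200, design200,
            h.SelectionScheme(strategy="A_pWgs", p_among=pa, p_within=pw,
                              r_accuracy=r), MEAN200)
        assert combined.delta_g_abs > among
        gs = h.predict_gain(
            vc200, design200,
            h.SelectionScheme(strategy="A_gsWgs", p_among=pa, p_within=pw,
                              r_accuracy=r, cycle_years=1), MEAN200)
        assert gs.annual_pct > combined.annual_pct
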