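"""Closed-form 4-b estimators: exactness, printed-formula fidelity, algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import breastdwi as bd
from breastdwi.errors import ValidationError
from breastdwi.fourb import DEFAULT_QUADRUPLE, FourBSignals, estimates_table


def make_four_b(tissue, mode="assumption_matched", quad=DEFAULT_QUADRUPLE):
    return bd.four_b_from_tissue(tissue, quad, mode=mode)


class TestAdcTwoPoint:
    def test_inverts_exponential(self):
        assert bd.adc_two_point(1.0, 0.0, math.exp(-0.8), 800.0) == \
            pytest.approx(1.0e-3, rel=1e-12)

    def test_equal_signals_give_zero(self):
        assert bd.adc_two_point(0.7, 0.0, 0.7, 800.0) == 0.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError, match="signals"):
            bd.adc_two_point(-1.0, 0.0, 0.5, 800.0)
        with pytest.raises(ValidationError, match="b"):
            bd.adc_two_point(1.0, 800.0, 0.5, 0.0)

    def test_adc_decreases_with_b_for_kurtotic_tissue(self):
        # two-point ADC from (0, b) shrinks as b grows when K > 0
        t = bd.TissueState(f_ivim=0.0, adc0=1.0e-3, kurtosis=1.0)
        scheme = bd.AcquisitionScheme((0.0, 800.0, 1500.0))
        s = bd.ivim_kurtosis_signal(scheme, t, mode="physical").amplitudes
        adc_800 = bd.adc_two_point(s[0], 0.0, s[1], 800.0)
        adc_1500 = bd.adc_two_point(s[0], 0.0, s[2], 1500.0)
        assert adc_1500 < adc_800 < t.adc0


class TestShiftedAdc:
    def test_gaussian_signal_gives_adc0(self):
        fb = make_four_b(bd.TissueState(adc0=1.3e-3))
        assert bd.shifted_adc(fb) == pytest.approx(1.3e-3, rel=1e-12)

    @given(adc0=st.floats(0.5e-3, 2.5e-3), k=st.floats(0, 1.5))
    def test_matches_symbolic_expansion(self, adc0, k):
        # model identity: sADC = ADC0 - (b1+b3) * ADC0^2 K / 6
        fb = make_four_b(bd.TissueState(adc0=adc0, kurtosis=k))
        expected = adc0 - (200.0 + 1500.0) * adc0**2 * k / 6.0
        assert bd.shifted_adc(fb) == pytest.approx(expected, rel=1e-12)

    def test_equal_signals_give_zero(self):
        fb = FourBSignals(0.0, 200.0, 800.0, 1500.0, 1.0, 0.5, 0.5, 0.5)
        assert bd.shifted_adc(fb) == 0.0


class TestSlopeSet:
    def test_mono_exponential_collapses(self):
        fb = make_four_b(bd.TissueState(adc0=1.1e-3))
        s = bd.slope_set(fb)
        for v in (s.d1, s.d2, s.d3, s.sadc):
            assert v == pytest.approx(1.1e-3, rel=1e-12)
        assert s.f_first_pass == pytest.approx(0.0, abs=1e-12)
        assert s.h == pytest.approx(0.0, abs=1e-15)
        assert s.a == pytest.approx(0.0, abs=1e-15)

    def test_pure_kurtosis_yields_spurious_first_pass_fraction(self):
        # F = 1 - exp(-A_true b1 b2) > 0 even though f = 0: a documented
        # artifact of the printed formulas
        adc0, k = 1.0e-3, 1.0
        fb = make_four_b(bd.TissueState(adc0=adc0, kurtosis=k))
        s = bd.slope_set(fb)
        a_true = adc0**2 * k / 6.0
        expected_f1 = 1.0 - math.exp(-a_true * 200.0 * 800.0)
        assert s.f_first_pass == pytest.approx(expected_f1, rel=1e-9)

    def test_pure_ivim_first_pass_fraction_exact(self):
        fb = make_four_b(bd.TissueState(f_ivim=0.10, adc0=1.0e-3))
        s = bd.slope_set(fb)
        assert s.f_first_pass == pytest.approx(0.10, abs=1e-12)


class TestEstimateFivim:
    def test_mono_exponential_gives_zero(self):
        fb = make_four_b(bd.TissueState(adc0=1.0e-3))
        s = bd.slope_set(fb)
        assert bd.estimate_fivim(s, fb.b_quadruple) == pytest.approx(0.0, abs=1e-12)

    def test_k0_recovery_exact(self):
        fb = make_four_b(bd.TissueState(f_ivim=0.10, adc0=1.2e-3))
        s = bd.slope_set(fb)
        assert bd.estimate_fivim(s, fb.b_quadruple) == \
            pytest.approx(0.10, abs=1e-12)

    def test_k_positive_bias_is_finite(self):
        fb = make_four_b(bd.TissueState(f_ivim=0.10, adc0=1.0e-3, kurtosis=1.0))
        s = bd.slope_set(fb)
        f_hat = bd.estimate_fivim(s, fb.b_quadruple)
        assert np.isfinite(f_hat) and 0 <= f_hat < 1
        assert f_hat != pytest.approx(0.10, abs=1e-6)  # biased, by design


class TestEstimateAdc0:
    def test_k0_both_modes_give_sadc(self):
        fb = make_four_b(bd.TissueState(f_ivim=0.0, adc0=1.4e-3))
        s = bd.slope_set(fb)
        for mode in ("derived_sum", "paper_product"):
            assert bd.estimate_adc0(s, fb.b_quadruple, mode) == \
                pytest.approx(1.4e-3, rel=1e-12)

    def test_derived_sum_exact_paper_product_far(self):
        # with the model-true correction A = ADC0^2 K / 6, the sum form
        # recovers ADC0 exactly while the printed product form is far off
        adc0, k = 1.2e-3, 0.8
        fb = make_four_b(bd.TissueState(adc0=adc0, kurtosis=k))
        a_true = adc0**2 * k / 6.0
        s = bd.slope_set(fb)
        s_true = bd.SlopeSet(s.d1, s.d2, s.d3, s.sadc, s.f_first_pass,
                             s.h, a_true)
        exact = bd.estimate_adc0(s_true, fb.b_quadruple, "derived_sum")
        printed = bd.estimate_adc0(s_true, fb.b_quadruple, "paper_product")
        assert exact == pytest.approx(adc0, rel=1e-9)
        assert abs(printed - adc0) / adc0 > 1.0  # > 100% off

    def test_as_printed_pipeline_residual_bias_is_moderate(self):
        # the as-printed A inherits the spurious first-pass fraction for
        # f=0, K>0, so even derived_sum carries a few-percent bias there
        fb = make_four_b(bd.TissueState(adc0=1.2e-3, kurtosis=0.8))
        s = bd.slope_set(fb)
        approx = bd.estimate_adc0(s, fb.b_quadruple, "derived_sum")
        rel = abs(approx - 1.2e-3) / 1.2e-3
        assert 1e-3 < rel < 0.1

    def test_unknown_mode_rejected(self):
        fb = make_four_b(bd.TissueState())
        with pytest.raises(ValidationError, match="correction_mode"):
            bd.estimate_adc0(bd.slope_set(fb), fb.b_quadruple, "bogus")


class TestEstimateKurtosis:
    def test_zero_a_gives_zero_k(self):
        assert bd.estimate_kurtosis(0.0, 1.0e-3) == 0.0

    def test_identity_a_equals_adc0sq_k_over_6(self):
        adc0, k = 1.0e-3, 1.0
        assert bd.estimate_kurtosis(adc0**2 * k / 6.0, adc0) == \
            pytest.approx(k, rel=1e-12)

    def test_negative_a_preserved(self):
        assert bd.estimate_kurtosis(-1e-8, 1.0e-3) < 0

    def test_nonpositive_adc0_rejected(self):
        with pytest.raises(ValidationError, match="adc0"):
            bd.estimate_kurtosis(1e-8, 0.0)


class TestEstimateNoIvim:
    def test_mono_exponential(self):
        fb = make_four_b(bd.TissueState(adc0=1.0e-3))
        adc0, k = bd.estimate_no_ivim(fb)
        assert adc0 == pytest.approx(1.0e-3, rel=1e-12)
        assert k == pytest.approx(0.0, abs=1e-9)

    @given(adc0=st.floats(0.5e-3, 2.5e-3), k=st.floats(0, 1.5))
    def test_exact_recovery_derived_sum(self, adc0, k):
        fb = make_four_b(bd.TissueState(adc0=adc0, kurtosis=k))
        adc0_hat, k_hat = bd.estimate_no_ivim(fb)
        assert adc0_hat == pytest.approx(adc0, rel=1e-9)
        assert k_hat == pytest.approx(k, rel=1e-9, abs=1e-9)

    def test_violated_assumption_biases_estimates(self):
        fb = make_four_b(bd.TissueState(f_ivim=0.1, adc0=1.2e-3, kurtosis=0.8))
        adc0_hat, k_hat = bd.estimate_no_ivim(fb)
        assert abs(adc0_hat - 1.2e-3) / 1.2e-3 > 1e-3
        assert np.isfinite(k_hat)


class TestEstimate4b:
    @pytest.mark.parametrize("method", ["exact_closed_form", "as_printed",
                                        "no_ivim"])
    def test_gaussian_identity_every_method(self, method):
        fb = make_four_b(bd.TissueState(adc0=1.5e-3))
        est = bd.estimate_4b(fb, method=method)
        assert est.f_ivim_hat == pytest.approx(0.0, abs=1e-12)
        assert est.adc0_hat == pytest.approx(1.5e-3, rel=1e-12)
        assert est.k_hat == pytest.approx(0.0, abs=1e-9)

    @given(f=st.floats(0, 0.3), adc0=st.floats(0.5e-3, 2.5e-3),
           k=st.floats(0, 1.5))
    def test_exact_closed_form_full_recovery(self, f, adc0, k):
        fb = make_four_b(bd.TissueState(f_ivim=f, adc0=adc0, kurtosis=k))
        est = bd.estimate_4b(fb, method="exact_closed_form")
        assert est.f_ivim_hat == pytest.approx(f, rel=1e-9, abs=1e-11)
        assert est.adc0_hat == pytest.approx(adc0, rel=1e-9)
        assert est.k_hat == pytest.approx(k, rel=1e-9, abs=1e-9)

    def test_physical_synthesis_biases_fraction(self):
        # residual perfusion at b1=200 (finite D*) biases the estimate
        t = bd.TissueState(f_ivim=0.08, adc0=1.0e-3, kurtosis=1.0)
        fb = make_four_b(t, mode="physical")
        est = bd.estimate_4b(fb, method="exact_closed_form")
        assert est.f_ivim_hat != pytest.approx(0.08, abs=1e-4)
        assert abs(est.f_ivim_hat - 0.08) < 0.05  # small residual bias

    def test_negative_kurtosis_flagged_not_clamped(self):
        fb = make_four_b(bd.TissueState(adc0=1.2e-3))
        # perturb s_b3 downward: apparently faster-than-exponential decay
        # at high b, so D2 < D3 and A (hence K) goes negative
        fb2 = FourBSignals(*fb.b_quadruple, fb.s_b0, fb.s_b1, fb.s_b2,
                           fb.s_b3 * 0.98)
        est = bd.estimate_4b(fb2, method="exact_closed_form")
        assert est.k_hat < 0
        assert "negative_kurtosis" in est.flagged()

    def test_unknown_method_rejected(self):
        fb = make_four_b(bd.TissueState())
        with pytest.raises(ValidationError, match="method"):
            bd.estimate_4b(fb, method="bogus")

    def test_vectorized_agrees_with_scalar(self, rng):
        tissues = [bd.TissueState(f_ivim=f, adc0=a, kurtosis=k)
                   for f, a, k in zip(rng.uniform(0, 0.3, 10),
                                      rng.uniform(0.5e-3, 2.5e-3, 10),
                                      rng.uniform(0, 1.5, 10))]
        sigs = np.array([make_four_b(t).signals for t in tissues])
        fb = FourBSignals(*DEFAULT_QUADRUPLE, sigs[:, 0], sigs[:, 1],
                          sigs[:, 2], sigs[:, 3])
        batch = bd.estimate_4b(fb, method="as_printed")
        for i, t in enumerate(tissues):
            single = bd.estimate_4b(make_four_b(t), method="as_printed")
            assert batch.f_ivim_hat[i] == pytest.approx(single.f_ivim_hat,
                                                        rel=1e-12, abs=1e-14)
            assert batch.adc0_hat[i] == pytest.approx(single.adc0_hat,
                                                      rel=1e-12)

    def test_nonmonotone_input_flagged(self):
        fb = FourBSignals(0.0, 200.0, 800.0, 1500.0, 1.0, 0.8, 0.85, 0.3)
        est = bd.estimate_4b(fb)
        assert "nonmonotone_input" in est.flagged()


class TestSadcOrdering:
    @given(adc0=st.floats(0.5e-3, 2.5e-3), k=st.floats(0.05, 1.5))
    def test_sadc_below_two_point_below_adc0(self, adc0, k):
        # sADC(200,1500) < ADC(0,800) < ADC0 for f=0, K>0
        fb = make_four_b(bd.TissueState(adc0=adc0, kurtosis=k))
        adc_0_800 = bd.adc_two_point(fb.s_b0, 0.0, fb.s_b2, 800.0)
        assert bd.shifted_adc(fb) < adc_0_800 < adc0


class TestBatchTable:
    def test_estimates_table_shape_and_flags(self):
        sigs = np.array([make_four_b(bd.TissueState(adc0=a)).signals
                         for a in (1.0e-3, 1.5e-3, 2.0e-3)])
        fb = FourBSignals(*DEFAULT_QUADRUPLE, sigs[:, 0], sigs[:, 1],
                          sigs[:, 2], sigs[:, 3])
        frame = estimates_table(fb)
        assert len(frame) == 3
        np.testing.assert_allclose(frame["adc0_hat"],
                                   [1.0e-3, 1.5e-3, 2.0e-3], rtol=1e-9)
        assert any(c.startswith("qc_") for c in frame.columns)


class TestDiscrepancyReport:
    def test_report_documents_product_form_deviation(self):
        rep = bd.discrepancy_report()
        assert np.all(np.abs(rep["rel_err_derived_sum"]) < 1e-9)
        with_k = rep[rep["k_true"] > 0]
        assert np.all(np.abs(with_k["rel_err_paper_product"]) > 0.5)
        without_k = rep[rep["k_true"] == 0]
        assert np.all(np.abs(without_k["rel_err_paper_product"]) < 1e-9)
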