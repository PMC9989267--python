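"""Forward signal model behaviour: normalization, nesting, validity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import breastdwi as bd
from breastdwi.errors import ModelValidityError, ValidationError


class TestAcquisitionScheme:
    def test_rejects_unsorted_and_duplicate_b(self):
        with pytest.raises(ValidationError, match="b_values"):
            bd.AcquisitionScheme((0.0, 800.0, 200.0))
        with pytest.raises(ValidationError, match="b_values"):
            bd.AcquisitionScheme((0.0, 200.0, 200.0))
        with pytest.raises(ValidationError, match="b_values"):
            bd.AcquisitionScheme((0.0,))

    def test_directions_must_be_unit(self):
        with pytest.raises(ValidationError, match="directions"):
            bd.AcquisitionScheme((0.0, 800.0),
                                 directions=np.array([[0, 0, 1], [0, 0, 2.0]]))


class TestTissueState:
    @pytest.mark.parametrize("field,value", [
        ("s0", -1.0), ("adc0", 0.0), ("f_ivim", 1.0), ("f_ivim", -0.1),
        ("kurtosis", -0.5), ("d_star", -1e-3),
    ])
    def test_validation_names_offending_field(self, field, value):
        with pytest.raises(ValidationError, match=field):
            bd.TissueState(**{field: value})


class TestIvimSignal:
    def test_amplitude_at_b0_equals_s0(self):
        t = bd.TissueState(s0=123.0, f_ivim=0.2, adc0=1.3e-3)
        curve = bd.ivim_signal(bd.AcquisitionScheme((0.0, 500.0)), t)
        assert curve.amplitudes[0] == pytest.approx(123.0, rel=1e-12)

    def test_pure_tissue_is_mono_exponential(self):
        t = bd.TissueState(f_ivim=0.0, adc0=1.0e-3)
        curve = bd.ivim_signal(bd.AcquisitionScheme((0.0, 1000.0)), t)
        assert curve.amplitudes[1] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_biexponential_matches_scalar_arithmetic(self):
        # independent per-point evaluation of the bi-exponential
        f, ds, db, adc0 = 0.1, 10e-3, 1.7e-3, 1.0e-3
        bs = (0.0, 50.0, 100.0, 200.0)
        t = bd.TissueState(f_ivim=f, d_star=ds, d_blood=db, adc0=adc0)
        curve = bd.ivim_signal(bd.AcquisitionScheme(bs), t)
        for b, amp in zip(bs, curve.amplitudes):
            expected = (f * math.exp(-b * (ds + db))
                        + (1 - f) * math.exp(-b * adc0))
            assert amp == pytest.approx(expected, rel=1e-12)
        # fast initial decay then mono-exponential tail
        drops = -np.diff(np.log(curve.amplitudes)) / np.diff(bs)
        assert drops[0] > drops[-1]

    @given(f=st.floats(0, 0.3), adc0=st.floats(0.5e-3, 2.5e-3))
    def test_strictly_decreasing_in_b(self, f, adc0):
        t = bd.TissueState(f_ivim=f, adc0=adc0)
        curve = bd.ivim_signal(
            bd.AcquisitionScheme((0.0, 100.0, 500.0, 1000.0, 2000.0)), t)
        assert np.all(np.diff(curve.amplitudes) < 0)


class TestIvimKurtosisSignal:
    def test_k0_reduces_to_ivim(self, quad_scheme):
        t = bd.TissueState(f_ivim=0.15, adc0=1.4e-3, kurtosis=0.0)
        a = bd.ivim_signal(quad_scheme, t).amplitudes
        b = bd.ivim_kurtosis_signal(quad_scheme, t, mode="physical").amplitudes
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_log_signal_is_downward_parabola(self):
        t = bd.TissueState(f_ivim=0.0, adc0=1.0e-3, kurtosis=1.0)
        scheme = bd.AcquisitionScheme((0.0, 200.0, 800.0, 1500.0))
        curve = bd.ivim_kurtosis_signal(scheme, t, mode="physical")
        b = scheme.b_array
        expected = np.exp(-b * 1e-3 + (b * 1e-3) ** 2 / 6.0)
        np.testing.assert_allclose(curve.amplitudes, expected, rtol=1e-12)
        coef = np.polyfit(b, np.log(curve.amplitudes), 2)
        assert coef[0] > 0  # upward quadratic coefficient = kurtosis curvature

    def test_assumption_matched_perfusion_only_at_bmin(self, quad_scheme):
        t = bd.TissueState(f_ivim=0.1, adc0=1.0e-3, kurtosis=0.0)
        curve = bd.ivim_kurtosis_signal(quad_scheme, t,
                                        mode="assumption_matched")
        assert curve.amplitudes[0] == pytest.approx(1.0, rel=1e-12)
        mono = np.exp(-quad_scheme.b_array[1:] * 1e-3)
        np.testing.assert_allclose(curve.amplitudes[1:] / mono, 0.9,
                                   rtol=1e-12)

    def test_physical_mode_refuses_b_beyond_turnover(self):
        t = bd.TissueState(adc0=2.0e-3, kurtosis=1.5)  # turnover at 1000
        scheme = bd.AcquisitionScheme((0.0, 200.0, 800.0, 1500.0))
        with pytest.raises(ModelValidityError, match="1000"):
            bd.ivim_kurtosis_signal(scheme, t, mode="physical")

    def test_unknown_mode_rejected(self, quad_scheme):
        with pytest.raises(ValidationError, match="mode"):
            bd.ivim_kurtosis_signal(quad_scheme, bd.TissueState(), mode="bogus")

    @given(adc0=st.floats(0.5e-3, 2.5e-3), k=st.floats(0.1, 1.5),
           f=st.floats(0, 0.3))
    def test_monotone_within_validity(self, adc0, k, f):
        t = bd.TissueState(f_ivim=f, adc0=adc0, kurtosis=k)
        bmax = bd.validity_bmax(t)
        bs = tuple(np.linspace(0, min(bmax, 2500.0), 8))
        curve = bd.ivim_kurtosis_signal(bd.AcquisitionScheme(bs), t,
                                        mode="physical")
        assert np.all(np.diff(curve.amplitudes) < 0)

    @given(adc0=st.floats(0.5e-3, 2.5e-3), k=st.floats(0, 1.5),
           f=st.floats(0, 0.3), scale=st.floats(0.5, 2.0))
    def test_unit_rescaling_invariance(self, adc0, k, f, scale):
        """b -> b*s with all diffusivities -> d/s leaves every exponent
        (hence every amplitude) unchanged: the dimensional audit."""
        t1 = bd.TissueState(f_ivim=f, adc0=adc0, kurtosis=k)
        t2 = bd.TissueState(f_ivim=f, adc0=adc0 / scale, kurtosis=k,
                            d_star=t1.d_star / scale,
                            d_blood=t1.d_blood / scale)
        bs = np.array([0.0, 200.0, 800.0, 1500.0])
        c1 = bd.ivim_kurtosis_signal(bd.AcquisitionScheme(tuple(bs)), t1,
                                     mode="assumption_matched").amplitudes
        c2 = bd.ivim_kurtosis_signal(bd.AcquisitionScheme(tuple(bs * scale)),
                                     t2, mode="assumption_matched").amplitudes
        np.testing.assert_allclose(c1, c2, rtol=1e-12)


class TestValidityBmax:
    def test_known_values(self):
        assert bd.validity_bmax(bd.TissueState(kurtosis=0.0)) == math.inf
        assert bd.validity_bmax(
            bd.TissueState(adc0=1.0e-3, kurtosis=1.0)) == pytest.approx(3000.0)
        assert bd.validity_bmax(
            bd.TissueState(adc0=2.0e-3, kurtosis=1.5)) == pytest.approx(1000.0)


class TestSignalCurve:
    def test_table_round_trip(self, tmp_path, quad_scheme):
        curve = bd.ivim_signal(quad_scheme, bd.TissueState(s0=50.0))
        path = tmp_path / "curve.txt"
        curve.to_table(path)
        back = bd.SignalCurve.from_table(path)
        np.testing.assert_allclose(back.amplitudes, curve.amplitudes,
                                   rtol=1e-9)
        assert back.scheme.b_values == quad_scheme.b_values

    def test_normalize(self, quad_scheme):
        curve = bd.ivim_signal(quad_scheme, bd.TissueState(s0=10.0))
        norm = curve.normalize()
        assert norm.normalized and norm.amplitudes[0] == 1.0
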