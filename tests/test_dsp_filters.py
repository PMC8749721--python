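"""Filter designs and the direct-form-II application path."""

import numpy as np
import pytest
from scipy import signal

from biopad import dsp_filters as d
from biopad import eeg_pipeline, synth_stream


def df2_reference(x, b, a):
    """Independent oracle: the textbook direct-form-II recursion
    w(n) = x(n) − Σ a_i w(n−i);  y(n) = Σ b_j w(n−j), zero initial state."""
    nb, na = len(b), len(a)
    order = max(nb, na) - 1
    w = np.zeros(order + 1)
    y = np.empty_like(np.asarray(x, dtype=float))
    for n, xn in enumerate(x):
        w[1:] = w[:-1]
        w[0] = xn - sum(a[i] * w[i] for i in range(1, na))
        y[n] = sum(b[j] * w[j] for j in range(nb))
    return y


class TestCombDesign:
    def setup_method(self):
        self.comb = d.design_comb()

    def test_mains_notch_depth_at_least_20_4_db(self):
        for f in (50.0, 100.0, 150.0):
            assert d.attenuation_db(self.comb, f) >= 20.4

    def test_dc_is_also_notched(self):
        assert d.attenuation_db(self.comb, 0.0) >= 20.4

    def test_inter_notch_midpoints_are_exactly_unity_gain(self):
        for f in (25.0, 75.0, 125.0, 175.0):
            assert d.attenuation_db(self.comb, f) == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_response_symmetric_about_each_notch(self):
        for fk in (50.0, 100.0, 150.0):
            for delta in (0.5, 2.0, 5.0):
                below = d.attenuation_db(self.comb, fk - delta)
                above = d.attenuation_db(self.comb, fk + delta)
                assert below == pytest.approx(above, abs=1e-9)

    def test_stable_and_unstable_coefficient_rejected(self):
        assert self.comb.is_stable()
        with pytest.raises(ValueError):
            d.design_comb(rh0=1.5)

    def test_difference_equation_form(self):
        # y(n) = (1+rh0)/2 [x(n) - x(n-N)] + rh0 y(n-N)
        g = (1 + d.COMB_RH0) / 2
        assert self.comb.b[0] == pytest.approx(g)
        assert self.comb.b[8] == pytest.approx(-g)
        assert self.comb.a[8] == pytest.approx(-d.COMB_RH0)


class TestButterworthDesign:
    def setup_method(self):
        self.lp = d.design_butterworth_lp(2, 30.0, 400.0)

    def test_corner_is_3db_point(self):
        assert d.attenuation_db(self.lp, 30.0) == pytest.approx(3.0103,
                                                                abs=0.01)

    def test_unity_dc_gain(self):
        assert d.attenuation_db(self.lp, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_prewarped_analytic_magnitude(self):
        # oracle: |H(jw)|^2 = 1/(1+(w/wc)^4) with bilinear pre-warping
        fs = 400.0
        warp = lambda f: 2 * fs * np.tan(np.pi * f / fs)
        for f in (10.0, 30.0, 60.0, 90.0, 150.0):
            expected = -10 * np.log10(1 + (warp(f) / warp(30.0)) ** 4)
            got = d.frequency_response(self.lp, np.array([f])).magnitude_db[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_out_of_band_cutoff_rejected(self):
        with pytest.raises(ValueError):
            d.design_butterworth_lp(2, 250.0, 400.0)


class TestApplyIirDf2:
    def test_zero_input_zero_output(self):
        lp = d.design_butterworth_lp(2, 30.0, 400.0)
        assert np.all(d.apply_iir_df2(np.zeros(100), lp) == 0.0)

    def test_impulse_response_matches_partial_fraction_oracle(self):
        lp = d.design_butterworth_lp(2, 30.0, 400.0)
        x = np.zeros(200)
        x[0] = 1.0
        got = d.apply_iir_df2(x, lp)
        r, p, k = signal.residuez(lp.b, lp.a)
        n = np.arange(200)
        analytic = sum(ri * pi ** n for ri, pi in zip(r, p))
        if len(k):
            analytic[0] += k[0]
        assert np.allclose(got, analytic.real, atol=1e-12)

    def test_matches_difference_equation_oracle_sample_for_sample(self, rng):
        x = rng.standard_normal(10_000)
        for spec in (d.design_comb(), d.design_butterworth_lp(2, 30, 400)):
            assert np.allclose(d.apply_iir_df2(x, spec),
                               df2_reference(x, spec.b, spec.a), atol=1e-10)

    def test_mains_sine_suppressed_to_notch_depth(self):
        comb = d.design_comb()
        t = np.arange(4000) / 400.0
        y = d.apply_iir_df2(np.sin(2 * np.pi * 50 * t), comb)
        steady = y[2000:]
        assert np.abs(steady).max() <= 10 ** (-20.4 / 20)

    def test_linearity_and_time_invariance(self, rng):
        lp = d.design_butterworth_lp(2, 30.0, 400.0)
        x1, x2 = rng.standard_normal((2, 500))
        lhs = d.apply_iir_df2(3.0 * x1 - 2.0 * x2, lp)
        rhs = 3.0 * d.apply_iir_df2(x1, lp) - 2.0 * d.apply_iir_df2(x2, lp)
        assert np.allclose(lhs, rhs, atol=1e-12)
        shifted = np.concatenate([np.zeros(25), x1])
        assert np.allclose(d.apply_iir_df2(shifted, lp)[25:],
                           d.apply_iir_df2(x1, lp)[:500], atol=1e-12)

    def test_nonfinite_input_rejected(self):
        lp = d.design_butterworth_lp(2, 30.0, 400.0)
        with pytest.raises(ValueError):
            d.apply_iir_df2(np.array([0.0, np.nan]), lp)


class TestPeripheralDesigns:
    @pytest.mark.parametrize("channel, fc", [("EDA", 5.0), ("SKT", 1.0),
                                             ("PPG", 8.0)])
    def test_channel_cutoffs(self, channel, fc):
        spec = d.design_peripheral_lp(channel)
        assert spec.design["fc"] == fc
        assert spec.is_stable()

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            d.design_peripheral_lp("EMG")


class TestYamlRoundTrip:
    def test_spec_serializes_and_reloads(self, tmp_path):
        spec = d.design_comb()
        path = tmp_path / "comb.yaml"
        spec.to_yaml(path)
        back = d.IIRSpec.from_yaml(path)
        assert np.allclose(back.b, spec.b) and np.allclose(back.a, spec.a)
        assert back.fs == spec.fs


class TestEegChainOnBlinkFixture:
    def test_mains_removed_alpha_band_preserved(self):
        cfg = synth_stream.SessionConfig(
            duration_s=30.0, seed=5,
            eeg=synth_stream.EEGConfig(
                alpha_state_schedule=[(0, 30, "closed")], mains_amp_uv=20.0),
        )
        raw, _ = synth_stream.gen_eeg(cfg)
        filtered = d.eeg_filter_chain(raw[:, 0], 400.0)
        psd_raw = eeg_pipeline.welch_psd(raw[:, 0], 400.0)
        psd_filt = eeg_pipeline.welch_psd(filtered, 400.0)
        mains_before = eeg_pipeline.band_power(psd_raw, 49.0, 51.0).absolute
        mains_after = eeg_pipeline.band_power(psd_filt, 49.0, 51.0).absolute
        assert 10 * np.log10(mains_before / mains_after) >= 20.0
        low_before = eeg_pipeline.band_power(psd_raw, 1.0, 13.0).absolute
        low_after = eeg_pipeline.band_power(psd_filt, 1.0, 13.0).absolute
        assert abs(10 * np.log10(low_before / low_after)) <= 1.0
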