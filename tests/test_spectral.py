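"""Spectral estimation and band statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammacc import spectral
from gammacc.spectral import (
    BANDS,
    BandDefinition,
    PSDEstimate,
    change_power,
    compute_erp,
    delta_power,
    extract_window,
    fit_psd_slope,
    multitaper_psd,
    orientation_selectivity,
    spectrogram,
    ssvep_power,
)

FS = 500.0


def _epoch_time(n=900, fs=FS, t0=-1.0):
    return t0 + np.arange(n) / fs


class TestMultitaperPSD:
    def test_500ms_window_gives_2hz_resolution(self):
        x = np.zeros(250)
        psd = multitaper_psd(x + 1e-6, FS)
        assert psd.freqs[1] - psd.freqs[0] == pytest.approx(2.0)

    def test_on_grid_tone_peaks_at_its_bin(self):
        t = np.arange(250) / FS
        psd = multitaper_psd(np.sin(2 * np.pi * 40 * t), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(40.0)

    def test_parseval_on_deterministic_input(self):
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 40 * t) + 0.5 * np.sin(2 * np.pi * 12 * t + 0.3)
        psd = multitaper_psd(x, FS)
        df = psd.freqs[1] - psd.freqs[0]
        assert np.sum(psd.power) * df == pytest.approx(np.var(x), rel=0.01)

    def test_white_noise_spectrum_is_flat(self, rng):
        # 200 repeats; mean spectrum within 3 SE of the grand mean in 20-80 Hz
        x = rng.standard_normal((200, 250))
        psd = multitaper_psd(x, FS)
        per = multitaper_psd(x, FS, average=False).power
        band = (psd.freqs >= 20) & (psd.freqs <= 80)
        se = per[:, band].std(axis=0, ddof=1) / np.sqrt(200)
        grand = psd.power[band].mean()
        assert np.all(np.abs(psd.power[band] - grand) < 3 * se + 1e-12)

    def test_nan_segment_rejected(self):
        x = np.ones(250)
        x[3] = np.nan
        with pytest.raises(ValueError):
            multitaper_psd(x, FS)


class TestSpectrogram:
    def test_250ms_window_gives_4hz_resolution_and_25ms_steps(self, rng):
        time = _epoch_time()
        spec = spectrogram(rng.standard_normal(900), FS, time)
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(4.0)
        steps = np.diff(spec.times)
        assert steps.mean() == pytest.approx(0.025, abs=1e-4)
        assert np.all(np.abs(steps - 0.025) <= 1.0 / FS + 1e-9)

    def test_stationary_noise_has_flat_change_power(self, rng):
        time = _epoch_time()
        spec = spectrogram(rng.standard_normal((100, 900)), FS, time)
        cp = change_power(spec)
        assert abs(cp.mean()) < 0.5

    def test_too_short_epoch_raises(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(50), FS, _epoch_time(50))


class TestDeltaPower:
    def _psd(self, power, freqs=None):
        power = np.asarray(power, float)
        freqs = np.arange(power.size) * 2.0 if freqs is None else freqs
        return PSDEstimate(freqs=freqs, power=power)

    def test_identity_gives_zero_db(self):
        p = self._psd(np.full(50, 2.0))
        band = BANDS["slow_gamma"]
        assert delta_power(p, p, band).delta_power == pytest.approx(0.0)

    def test_tenfold_power_gives_10_db(self):
        bl = self._psd(np.full(50, 1.5))
        st = self._psd(np.full(50, 15.0))
        assert delta_power(st, bl, BANDS["alpha"]).delta_power == pytest.approx(10.0)

    def test_hand_example_sum_then_log(self):
        freqs = np.array([20.0, 22.0, 24.0])
        bl = self._psd([4.0, 2.0, 1.0], freqs)
        st = self._psd([8.0, 2.0, 1.0], freqs)
        res = delta_power(st, bl, BandDefinition("b", 20, 24))
        assert res.delta_power == pytest.approx(10 * np.log10(11 / 7), abs=1e-12)

    def test_band_edges_inclusive_on_grid(self):
        freqs = np.arange(0, 101, 2.0)
        p = self._psd(np.ones(freqs.size), freqs)
        res = delta_power(p, p, BANDS["slow_gamma"])
        assert res.bl_sum == pytest.approx(8.0)  # bins 20,22,...,34

    @settings(max_examples=40, deadline=None)
    @given(gain=st.floats(0.01, 100.0))
    def test_invariant_to_common_rescaling(self, gain):
        freqs = np.arange(0, 101, 2.0)
        rng = np.random.default_rng(7)
        blp = rng.uniform(0.5, 2.0, freqs.size)
        stp = rng.uniform(0.5, 2.0, freqs.size)
        band = BANDS["fast_gamma"]
        a = delta_power(self._psd(stp, freqs), self._psd(blp, freqs), band).delta_power
        b = delta_power(self._psd(gain * stp, freqs), self._psd(gain * blp, freqs),
                        band).delta_power
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_baseline_raises(self):
        freqs = np.arange(0, 101, 2.0)
        with pytest.raises(ValueError):
            delta_power(self._psd(np.ones(51), freqs), self._psd(np.zeros(51), freqs),
                        BANDS["alpha"])

    def test_empty_band_raises(self):
        freqs = np.array([0.0, 2.0])
        p = self._psd([1.0, 1.0], freqs)
        with pytest.raises(ValueError):
            delta_power(p, p, BandDefinition("hi", 50, 60))


class TestSlopeFit:
    def test_exact_power_law_recovered(self):
        f = np.arange(56.0, 85.0, 2.0)
        fit = fit_psd_slope(PSDEstimate(freqs=f, power=f**-2.0))
        assert fit.beta == pytest.approx(2.0, abs=1e-9)
        assert fit.A == pytest.approx(1.0, abs=1e-6)

    def test_scaled_power_law_recovered(self):
        f = np.arange(56.0, 85.0, 2.0)
        fit = fit_psd_slope(PSDEstimate(freqs=f, power=5.0 * f**-1.5))
        assert fit.beta == pytest.approx(1.5, abs=1e-6)
        assert fit.A == pytest.approx(5.0, abs=1e-4)

    def test_white_noise_slope_near_zero(self, rng):
        # 150 repeats x 10 channels: the averaged single-taper spectrum is
        # flat enough that the fitted exponent sits well inside +-0.15
        x = rng.standard_normal((150, 10, 250))
        psd = multitaper_psd(x, FS)
        fit = fit_psd_slope(psd)
        assert abs(fit.beta) < 0.15

    def test_refine_matches_closed_form_on_noiseless_data(self):
        f = np.arange(56.0, 85.0, 2.0)
        p = PSDEstimate(freqs=f, power=3.0 * f**-1.2)
        assert fit_psd_slope(p, refine=False).beta == pytest.approx(
            fit_psd_slope(p, refine=True).beta, abs=1e-6)

    def test_nonpositive_power_raises(self):
        f = np.arange(56.0, 85.0, 2.0)
        with pytest.raises(ValueError):
            fit_psd_slope(PSDEstimate(freqs=f, power=np.zeros(f.size)))


class TestOrientationSelectivity:
    @pytest.mark.parametrize(
        "R,expected",
        [((1, 1, 1, 1), 0.0), ((1, 0, 0, 0), 1.0), ((3, 1, 1, 1), 1 / 3)],
    )
    def test_hand_values(self, R, expected):
        assert orientation_selectivity(R) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4))
    def test_bounded_in_unit_interval(self, R):
        if sum(R) <= 0:
            return
        s = orientation_selectivity(R)
        assert -1e-12 <= s <= 1.0 + 1e-12

    def test_zero_power_undefined(self):
        with pytest.raises(ValueError):
            orientation_selectivity((0, 0, 0, 0))


class TestSSVEP:
    def test_response_frequency_for_16cps_is_32hz(self):
        # 2nd harmonic of the counterphase frequency lands on the 2 Hz grid
        assert 2 * 16 == 32
        time = _epoch_time()
        epochs = np.random.default_rng(0).standard_normal((20, 900))
        res = ssvep_power(epochs, FS, time)
        assert res.band.f_lo < 32.0 < res.band.f_hi

    def test_null_signal_near_zero_db(self, rng):
        time = _epoch_time()
        res = ssvep_power(rng.standard_normal((100, 900)), FS, time)
        assert abs(res.delta_power) < 1.0

    def test_stimulus_locked_tone_exceeds_10_db(self, rng):
        time = _epoch_time()
        epochs = rng.standard_normal((50, 900))
        tone = 3.0 * np.sin(2 * np.pi * 32 * time)
        epochs[:, time >= 0] += tone[time >= 0]
        res = ssvep_power(epochs, FS, time)
        assert res.delta_power > 10.0

    def test_off_grid_frequency_raises(self, rng):
        time = _epoch_time()
        with pytest.raises(ValueError):
            ssvep_power(rng.standard_normal((10, 900)), FS, time, freq=33.0)


class TestERP:
    def test_template_latencies_recovered(self, rng):
        from gammacc.synth import erp_template

        time = _epoch_time()
        epochs = erp_template(time, 3.0) + 0.5 * rng.standard_normal((100, 900))
        res = compute_erp(epochs, time)
        assert res.peaks["P1"][0] == pytest.approx(0.100, abs=0.010)
        assert res.peaks["N1"][0] == pytest.approx(0.170, abs=0.010)
        assert res.peaks["P2"][0] == pytest.approx(0.230, abs=0.010)
        assert res.peaks["P1"][0] < res.peaks["N1"][0] < res.peaks["P2"][0]
        assert res.peaks["N1"][1] < 0 < res.peaks["P1"][1]

    def test_zero_signal_peaks_are_small(self, rng):
        time = _epoch_time()
        epochs = rng.standard_normal((200, 900))
        res = compute_erp(epochs, time)
        se = 3.0 / np.sqrt(200)
        for _, amp in res.peaks.values():
            assert abs(amp) < 3 * se + 0.3

    def test_amplitude_scales_linearly_with_gain(self, rng):
        from gammacc.synth import erp_template

        time = _epoch_time()
        gains = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        noise = 0.3 * rng.standard_normal((40, 900))
        amps = []
        for g in gains:
            res = compute_erp(erp_template(time, g) + noise, time)
            amps.append(res.peaks["P2"][1])
        r = np.corrcoef(gains, amps)[0, 1]
        assert r > 0.99

    def test_too_few_repeats_raises(self):
        time = _epoch_time()
        with pytest.raises(ValueError):
            compute_erp(np.zeros((5, 900)), time)


class TestSpectrogramDeltaAgreement:
    def test_band_change_agrees_within_1_db(self, rng, healthy_subject, static_condition,
                                            oz_params):
        from dataclasses import replace
        from gammacc import synth

        p = replace(oz_params, gamma_amp={"slow": 2.0, "fast": 0.0}, erp_amp=0.0)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 150)
        data = np.stack([t.data[0] for t in block]).astype(float)
        time = block[0].time
        band = BANDS["slow_gamma"]

        st_psd = multitaper_psd(data[:, extract_window(time, 0.25, 0.75)], FS)
        bl_psd = multitaper_psd(data[:, extract_window(time, -0.5, 0.0)], FS)
        dp = delta_power(st_psd, bl_psd, band).delta_power

        spec = spectrogram(data, FS, time)
        fmask = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
        tmask = (spec.times >= 0.25 + 0.125) & (spec.times <= 0.75 - 0.125)
        blmask = (spec.times - 0.125 >= -0.5) & (spec.times + 0.125 <= 0.0)
        st_band = spec.power[np.ix_(tmask, fmask)].sum(axis=1).mean()
        bl_band = spec.power[np.ix_(blmask, fmask)].sum(axis=1).mean()
        sg = 10 * np.log10(st_band / bl_band)
        assert dp == pytest.approx(sg, abs=1.0)
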