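"""Generator contracts: determinism, injected structure, cohort matching."""

from dataclasses import replace

import numpy as np
import pytest

from gammacc import synth
from gammacc.spectral import (
    BANDS,
    delta_power,
    extract_window,
    fit_psd_slope,
    multitaper_psd,
    spectrogram,
)
from gammacc.synth import (
    GAMMA_EXPERIMENT_CONDITIONS,
    GeneratorParams,
    MatchingError,
    StimulusCondition,
    SubjectProfile,
    calibrate_gamma_amp,
    generate_cohort,
    generate_trial,
    inject_artifacts,
)

FS = 500.0


def _band_sums(block, band, channel=0):
    data = np.stack([t.data[channel] for t in block]).astype(float)
    time = block[0].time
    st = multitaper_psd(data[:, extract_window(time, 0.25, 0.75)], FS)
    bl = multitaper_psd(data[:, extract_window(time, -0.5, 0.0)], FS)
    return delta_power(st, bl, band)


class TestTrialGeneration:
    def test_same_seed_identical_samples(self, healthy_subject, static_condition, oz_params):
        a = generate_trial(healthy_subject, static_condition, oz_params,
                           np.random.default_rng(11))
        b = generate_trial(healthy_subject, static_condition, oz_params,
                           np.random.default_rng(11))
        assert np.array_equal(a.data, b.data)
        assert np.allclose(a.eye.x, b.eye.x, equal_nan=True)

    def test_epoch_and_channel_shape(self, healthy_subject, static_condition, oz_params, rng):
        tr = generate_trial(healthy_subject, static_condition, oz_params, rng)
        assert tr.time[0] <= -0.5 and tr.time[-1] >= 0.75
        assert tr.data.shape == (1, oz_params.n_samples)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            StimulusCondition(3, 0, 0)
        with pytest.raises(ValueError):
            StimulusCondition(2, 30, 0)

    def test_null_model_delta_power_near_zero(self, healthy_subject, static_condition, rng):
        # no gamma, no alpha suppression: stimulus and baseline band powers
        # match; averaged over 100 repeats x 10 channels because narrowband
        # alpha has few effective degrees of freedom per 500 ms window
        from gammacc.pipeline import ANALYSIS_ELECTRODES

        p = GeneratorParams(channels=ANALYSIS_ELECTRODES, artifact_rate=0.0,
                            gamma_amp={"slow": 0.0, "fast": 0.0}, alpha_suppression=1.0)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 100)
        data = np.stack([t.data for t in block]).astype(float)
        time = block[0].time
        st = multitaper_psd(data[..., extract_window(time, 0.25, 0.75)], FS)
        bl = multitaper_psd(data[..., extract_window(time, -0.5, 0.0)], FS)
        for band in ("alpha", "slow_gamma", "fast_gamma"):
            dp = delta_power(st, bl, BANDS[band]).delta_power
            assert abs(dp) < 0.3, band

    def test_forced_power_ratio_four_gives_6_dB(self, healthy_subject, static_condition,
                                                oz_params):
        amp = calibrate_gamma_amp(oz_params, "slow", 4.0)
        p = replace(oz_params, gamma_amp={"slow": amp, "fast": 0.0})
        block = synth._generate_block(healthy_subject, static_condition, p,
                                      np.random.default_rng(99), 100)
        dp = _band_sums(block, BANDS["slow_gamma"]).delta_power
        assert dp == pytest.approx(10 * np.log10(4.0), abs=0.3)

    def test_background_slope_recovered(self, healthy_subject, static_condition, rng):
        p = GeneratorParams(channels=("Oz", "POz", "O1", "O2"), alpha_power=0.0,
                            erp_amp=0.0, gamma_amp={"slow": 0.0, "fast": 0.0},
                            artifact_rate=0.0)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 60)
        data = np.stack([t.data for t in block]).astype(float)
        time = block[0].time
        psd = multitaper_psd(data[..., extract_window(time, -0.5, 0.0)], FS)
        fit = fit_psd_slope(psd)
        assert fit.beta == pytest.approx(p.background_beta, abs=0.15)

    def test_gamma_gated_on_after_onset(self, healthy_subject, static_condition, oz_params,
                                        rng):
        p = replace(oz_params, gamma_amp={"slow": 0.0, "fast": 4.0}, erp_amp=0.0,
                    alpha_power=0.0)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 80)
        data = np.stack([t.data[0] for t in block]).astype(float)
        time = block[0].time
        spec = spectrogram(data, FS, time)
        band = (spec.freqs >= 36) & (spec.freqs <= 66)
        bandpow = spec.power[:, band].sum(axis=1)
        pre = bandpow[spec.times + 0.125 <= -0.3].mean()
        late_pre = bandpow[(spec.times > -0.3) & (spec.times + 0.125 <= 0.0)].mean()
        post = bandpow[spec.times - 0.125 >= 0.1].mean()
        assert post / pre > 3.0
        assert late_pre / pre < 1.5  # still off immediately before onset

    def test_ssvep_trials_peak_at_32hz(self, healthy_subject, oz_params, rng):
        cond = StimulusCondition(2, 0, 16)
        block = synth._generate_block(healthy_subject, cond, oz_params, rng, 100)
        data = np.stack([t.data[0] for t in block]).astype(float)
        time = block[0].time
        st = multitaper_psd(data[:, extract_window(time, 0.25, 0.75)], FS)
        p32 = st.power[st.freqs == 32.0][0]
        p28 = st.power[st.freqs == 28.0][0]
        p36 = st.power[st.freqs == 36.0][0]
        assert p32 > p28 and p32 > p36

    def test_group_deficit_lowers_gamma_not_alpha(self, static_condition):
        from gammacc.pipeline import ANALYSIS_ELECTRODES

        healthy = SubjectProfile("h000", 70, "male", "healthy", 0.0)
        mci = SubjectProfile("m000", 70, "male", "MCI", 0.5)
        p = GeneratorParams(channels=ANALYSIS_ELECTRODES, artifact_rate=0.0)
        deltas = {}
        for prof in (healthy, mci):
            block = synth._generate_block(prof, static_condition, p,
                                          np.random.default_rng(5), 150)
            data = np.stack([t.data for t in block]).astype(float)
            time = block[0].time
            st = multitaper_psd(data[..., extract_window(time, 0.25, 0.75)], FS)
            bl = multitaper_psd(data[..., extract_window(time, -0.5, 0.0)], FS)
            deltas[prof.group] = {b: delta_power(st, bl, BANDS[b]).delta_power
                                  for b in ("alpha", "slow_gamma", "fast_gamma")}
        for band in ("slow_gamma", "fast_gamma"):
            assert deltas["MCI"][band] < deltas["healthy"][band] - 0.5, band
        assert deltas["MCI"]["alpha"] == pytest.approx(deltas["healthy"]["alpha"], abs=0.5)


class TestEyeTraceStructure:
    def test_fixation_sd_below_half_degree(self, healthy_subject, static_condition,
                                           oz_params, rng):
        block = synth._generate_block(healthy_subject, static_condition, oz_params, rng, 60)
        xs = np.concatenate([t.eye.x[~np.isnan(t.eye.x)] for t in block])
        ys = np.concatenate([t.eye.y[~np.isnan(t.eye.y)] for t in block])
        assert np.std(xs) < 0.5 and np.std(ys) < 0.5

    def test_main_sequence_correlation(self, healthy_subject, static_condition, oz_params,
                                       rng):
        from gammacc.eye import detect_microsaccades

        p = replace(oz_params, saccade_rate=1.2, blink_rate=0.0)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 150)
        events = [ev for t in block for ev in detect_microsaccades(t.eye)]
        assert len(events) > 50
        lv = np.log10([e.peak_velocity for e in events])
        ld = np.log10([e.max_displacement for e in events])
        assert np.corrcoef(ld, lv)[0, 1] > 0.8

    def test_blinks_are_nan_runs_in_all_streams(self, healthy_subject, static_condition,
                                                oz_params):
        p = replace(oz_params, blink_rate=3.0)
        rng = np.random.default_rng(8)
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 20)
        nan_counts = [np.isnan(t.eye.x).sum() for t in block]
        assert max(nan_counts) > 0
        for t in block:
            m = np.isnan(t.eye.x)
            assert np.array_equal(m, np.isnan(t.eye.y))
            assert np.array_equal(m, np.isnan(t.eye.pupil))


class TestInjectArtifacts:
    def test_rate_zero_leaves_data_unchanged(self, healthy_subject, static_condition,
                                             oz_params, rng):
        tr = generate_trial(healthy_subject, static_condition, oz_params, rng)
        p = replace(oz_params, artifact_rate=0.0)
        out = inject_artifacts(tr, p, np.random.default_rng(0))
        assert np.array_equal(out.data, tr.data)

    def test_rising_spectrum_trips_slope_sign(self, healthy_subject, static_condition,
                                              oz_params, rng):
        p = replace(oz_params, channels=("Oz", "POz"))
        block = synth._generate_block(healthy_subject, static_condition, p, rng, 40)
        block = [inject_artifacts(t, p, rng, mode="rising", electrodes=["POz"])
                 for t in block]
        data = np.stack([t.data for t in block]).astype(float)
        time = block[0].time
        psd = multitaper_psd(data[..., extract_window(time, -0.5, 0.0)][:, 1, :], FS)
        assert fit_psd_slope(psd).beta < 0

    def test_transient_exceeds_six_mads(self, healthy_subject, static_condition, oz_params,
                                        rng):
        p = replace(oz_params, artifact_rate=1.0)
        tr = generate_trial(healthy_subject, static_condition, p, rng)
        out = inject_artifacts(tr, p, np.random.default_rng(4), electrodes=["Oz"])
        assert np.max(np.abs(out.data)) > 6 * np.std(tr.data)


class TestCohort:
    def test_counts_and_guaranteed_matching(self):
        p = GeneratorParams(channels=("Oz",), seed=3)
        cohort = generate_cohort(4, 1, 1, 2, p,
                                 conditions=GAMMA_EXPERIMENT_CONDITIONS[:3])
        assert len(cohort) == 6
        profiles = [prof for prof, _ in cohort]
        healthy = [q for q in profiles if q.group == "healthy"]
        for case in [q for q in profiles if q.group != "healthy"]:
            assert any(abs(h.age - case.age) <= 1 and h.gender == case.gender
                       for h in healthy)
        for _, trials in cohort:
            assert len(trials) == 3 * 2  # conditions x repeats

    def test_twelve_cases_all_matched(self):
        p = GeneratorParams(channels=("Oz",), seed=1)
        cohort = generate_cohort(30, 12, 0, 1, p,
                                 conditions=GAMMA_EXPERIMENT_CONDITIONS[:1])
        profiles = [prof for prof, _ in cohort]
        healthy = [q for q in profiles if q.group == "healthy"]
        cases = [q for q in profiles if q.group == "MCI"]
        assert len(cases) == 12
        n_controls = [sum(abs(h.age - c.age) <= 1 and h.gender == c.gender for h in healthy)
                      for c in cases]
        assert min(n_controls) >= 1

    def test_impossible_matching_raises(self):
        with pytest.raises(MatchingError):
            generate_cohort(0, 1, 0, 1, GeneratorParams(channels=("Oz",)))

    def test_cohort_determinism(self):
        p = GeneratorParams(channels=("Oz",), seed=7)
        a = generate_cohort(2, 1, 0, 2, p, conditions=GAMMA_EXPERIMENT_CONDITIONS[:2])
        b = generate_cohort(2, 1, 0, 2, p, conditions=GAMMA_EXPERIMENT_CONDITIONS[:2])
        for (pa, ta), (pb, tb) in zip(a, b):
            assert pa == pb
            for x, y in zip(ta, tb):
                assert np.array_equal(x.data, y.data)

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            SubjectProfile("x", 70, "male", "healthy", 0.5)
        with pytest.raises(ValueError):
            SubjectProfile("x", 70, "male", "MCI", 0.0)
        with pytest.raises(ValueError):
            SubjectProfile("x", 40, "male", "healthy", 0.0)
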