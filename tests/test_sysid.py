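import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flygaze import sysid
from flygaze.signals import TimeSeries


def sine(f, fs=100.0, dur=20.0, amp=1.0, phase=0.0):
    t = np.arange(0, dur, 1 / fs)
    return TimeSeries(amp * np.sin(2 * np.pi * f * t + phase), fs)


class TestPreprocess:
    def test_removes_linear_ramp(self):
        t = np.arange(0, 10, 0.01)
        out = sysid.preprocess(TimeSeries(5.0 * t, 100.0))
        assert np.abs(out.values).max() < 1e-9 * 50.0

    def test_passband_amplitude_preserved(self):
        out = sysid.preprocess(sine(5.0))
        amp = np.abs(out.values[100:-100]).max()
        assert np.isclose(amp, 1.0, rtol=0.02)

    def test_stopband_attenuates(self):
        out45 = sysid.preprocess(sine(45.0))
        amp45 = np.sqrt(2 * np.mean(out45.values[200:-200] ** 2))
        assert amp45 < 0.1  # > 10x attenuation relative to the passband

    def test_rejects_low_sample_rate(self):
        with pytest.raises(ValueError, match="Nyquist"):
            sysid.preprocess(sine(5.0, fs=80.0))

    def test_rejects_short_data(self):
        with pytest.raises(ValueError, match="1 s"):
            sysid.preprocess(TimeSeries(np.zeros(50), 100.0))


class TestCztSpectrum:
    def test_zero_signal(self):
        _, s = sysid.czt_spectrum(TimeSeries(np.zeros(500), 100.0))
        assert np.all(s == 0)

    def test_unit_sine_magnitude_and_phase(self):
        freqs, s = sysid.czt_spectrum(sine(2.1, phase=0.7))
        i = sysid.grid_indices(freqs, [2.1])[0]
        assert np.isclose(np.abs(s[i]), 1.0, atol=1e-6)
        assert np.isclose(np.angle(s[i]), 0.7, atol=1e-6)

    def test_linearity(self):
        a, b = sine(2.1), sine(5.3, amp=0.5)
        both = TimeSeries(a.values + b.values, 100.0)
        _, sa = sysid.czt_spectrum(a)
        _, sb = sysid.czt_spectrum(b)
        _, sab = sysid.czt_spectrum(both)
        assert np.abs(sab - sa - sb).max() < 1e-9

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            sysid.czt_spectrum(sine(1.0), df=0.0)
        with pytest.raises(ValueError):
            sysid.czt_spectrum(sine(1.0), f_lo=10.0, f_hi=5.0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_direct_dft_sum(self, seed):
        """Chirp-z equals the direct normalized DFT sum on random signals."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        freqs, s = sysid.czt_spectrum(TimeSeries(x, 100.0))
        n = np.arange(x.size)
        check = freqs[::97]
        direct = np.array([
            (2j / x.size) * np.sum(x * np.exp(-2j * np.pi * f * n / 100.0))
            for f in check])
        assert np.abs(s[::97] - direct).max() < 1e-9


class TestFrf:
    def test_identity(self):
        ts = sine(2.1)
        fr = sysid.frf(ts, ts, [2.1]).at([2.1])
        assert np.isclose(fr.gain[0], 1.0, atol=1e-9)
        assert np.isclose(fr.phase[0], 0.0, atol=1e-9)

    def test_pure_delay_phase_law(self):
        # 50 ms delay: phase = -360 * f * 0.05 deg
        fs, delay = 100.0, 0.05
        t = np.arange(0, 20, 1 / fs)
        for f in (1.0, 2.1, 5.3):
            x = TimeSeries(np.sin(2 * np.pi * f * t), fs)
            y = TimeSeries(np.sin(2 * np.pi * f * (t - delay)), fs)
            fr = sysid.frf(x, y, [f]).at([f])
            assert np.isclose(fr.phase[0], sysid.wrap_phase_deg(-360 * f * delay),
                              atol=0.01)

    def test_first_order_lowpass_matches_analytic(self):
        from scipy import signal as sps
        fc = 3.0
        b, a = sps.butter(1, fc, fs=1000.0)
        t = np.arange(0, 20, 1e-3)
        for f in (0.7, 2.1, 5.3):
            x = np.sin(2 * np.pi * f * t)
            y = sps.lfilter(b, a, x)
            fr = sysid.frf(TimeSeries(x[4000:], 1000.0),
                           TimeSeries(y[4000:], 1000.0), [f]).at([f])
            _, h = sps.freqz(b, a, worN=[f], fs=1000.0)
            assert np.isclose(fr.gain[0], np.abs(h[0]), rtol=0.01)
            assert np.isclose(fr.phase[0], np.degrees(np.angle(h[0])), atol=1.0)

    def test_weak_input_flagged_not_divided(self):
        x = TimeSeries(np.zeros(2000), 100.0)
        y = sine(2.1)
        fr = sysid.frf(x, y, [2.1])
        assert not fr.valid[sysid.grid_indices(fr.freqs, [2.1])[0]]


class TestCompensationError:
    @pytest.mark.parametrize("value,expected", [
        (1 + 0j, 0.0),        # perfect compensation
        (0 + 0j, 1.0),        # no response
        (0 + 1j, np.sqrt(2)),  # gain 1 at 90 deg
    ])
    def test_endpoints(self, value, expected):
        fr = sysid.FrequencyResponse(freqs=np.array([1.0]),
                                     values=np.array([value]))
        assert np.isclose(sysid.compensation_error(fr).epsilon[0], expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(gain=st.floats(0.01, 3.0), phase=st.floats(-179.0, 179.0))
    def test_conjugation_symmetry(self, gain, phase):
        """eps is invariant under conjugating X (negating phase)."""
        mk = lambda p: sysid.FrequencyResponse.from_gain_phase(
            np.array([1.0]), np.array([gain]), np.array([p]))
        e1 = sysid.compensation_error(mk(phase)).epsilon[0]
        e2 = sysid.compensation_error(mk(-phase)).epsilon[0]
        assert np.isclose(e1, e2, rtol=1e-9)


class TestCoherence:
    def test_identical_trials_give_one(self):
        rng = np.random.default_rng(0)
        ins = [TimeSeries(rng.standard_normal(1000), 100.0) for _ in range(5)]
        coh = sysid.coherence(ins, ins, [2.1, 5.3])
        assert np.allclose(coh, 1.0)

    def test_independent_noise_gives_low_coherence(self):
        rng = np.random.default_rng(1)
        ins = [TimeSeries(rng.standard_normal(1000), 100.0) for _ in range(20)]
        outs = [TimeSeries(rng.standard_normal(1000), 100.0) for _ in range(20)]
        coh = sysid.coherence(ins, outs, [0.7, 2.1, 10.6])
        assert np.all(coh < 0.2)

    def test_noisy_filter_intermediate(self):
        # coherence = 1/(1 + N/S) = 0.5 at equal signal and noise power;
        # averaged over several bins to tame per-bin estimator scatter
        rng = np.random.default_rng(2)
        ins, outs = [], []
        for _ in range(40):
            x = rng.standard_normal(2000)
            ins.append(TimeSeries(x, 100.0))
            outs.append(TimeSeries(0.5 * x + 0.5 * rng.standard_normal(2000),
                                   100.0))
        coh = sysid.coherence(ins, outs, [0.7, 2.1, 5.3, 10.6])
        assert 0.35 < coh.mean() < 0.65

    def test_single_trial_rejected(self):
        ts = sine(2.1)
        with pytest.raises(ValueError, match="2 trials"):
            sysid.coherence([ts], [ts], [2.1])

    def test_closed_loop_trials_high_vs_shuffled_low(self, components):
        """Simulated closed-loop responses cohere with the stimulus (~1);
        replacing the responses with unrelated noise destroys it."""
        from flygaze import flysim
        from flygaze.perturbations import single_sine_spec
        spec = single_sine_spec(2.1, 250.0, 12.0, 100.0)
        ins, outs = [], []
        for seed in range(3):
            cfg = flysim.SimulationConfig(mode="body_free", seed=seed,
                                          noise_std_head=0.1,
                                          noise_std_body=0.1)
            trial = flysim.simulate_trial(components, spec, cfg)
            ins.append(sysid.preprocess(trial.R.crop(2.0)))
            outs.append(sysid.preprocess(trial.H.crop(2.0)))
        assert sysid.coherence(ins, outs, [2.1])[0] >= 0.99
        # under independence the estimator's expectation is 1/n_trials, so
        # use enough trials for the bound to be meaningful
        rng = np.random.default_rng(0)
        ins20 = [ins[0]] * 20
        noise = [ins[0].with_values(rng.standard_normal(len(ins[0])))
                 for _ in range(20)]
        assert sysid.coherence(ins20, noise, [2.1])[0] <= 0.2


class TestLssaAndSaturation:
    def test_clean_sine_amplitude(self):
        amp, phase, off = sysid.lssa_fit(sine(2.1, phase=0.3), 2.1)
        assert np.isclose(amp, 1.0, atol=1e-6)
        assert np.isclose(phase, np.degrees(0.3), atol=1e-4)

    def test_clipped_sine_with_mask_recovers(self):
        ts = sine(1.0)
        clipped = ts.with_values(np.clip(ts.values, -0.8, 0.8))
        mask = np.abs(clipped.values) >= 0.8 * 0.999
        amp_masked, _, _ = sysid.lssa_fit(clipped, 1.0, exclude_mask=mask)
        amp_unmasked, _, _ = sysid.lssa_fit(clipped, 1.0)
        assert np.isclose(amp_masked, 1.0, rtol=0.02)
        assert amp_unmasked < 0.95  # clipping biases the unmasked fit low

    def test_insufficient_unmasked_data_rejected(self):
        ts = sine(1.0)
        with pytest.raises(ValueError):
            sysid.lssa_fit(ts, 1.0, exclude_mask=np.ones(len(ts), dtype=bool))

    def test_saturation_correction_recovers_20deg_from_15deg_clip(self):
        t = np.arange(0, 10, 0.01)
        ts = TimeSeries(np.clip(20 * np.sin(2 * np.pi * t), -15, 15), 100.0)
        factor, mask = sysid.saturation_correct(ts, 1.0, 15.0)
        freqs, s = sysid.czt_spectrum(ts)
        corrected = factor * np.abs(s[sysid.grid_indices(freqs, [1.0])[0]])
        assert mask.any()
        assert np.isclose(corrected, 20.0, rtol=0.05)

    def test_unsaturated_trace_factor_one(self):
        ts = sine(1.0, amp=5.0, dur=10.0)
        factor, mask = sysid.saturation_correct(ts, 1.0, 15.0)
        assert not mask.any()
        assert np.isclose(factor, 1.0, rtol=1e-3)

    def test_correction_leaves_phase_alone(self):
        """The factor rescales gain only; phase comes from the untouched czt."""
        t = np.arange(0, 10, 0.01)
        ts = TimeSeries(np.clip(20 * np.sin(2 * np.pi * t + 0.4), -15, 15),
                        100.0)
        freqs, s = sysid.czt_spectrum(ts)
        before = np.angle(s[sysid.grid_indices(freqs, [1.0])[0]])
        sysid.saturation_correct(ts, 1.0, 15.0)
        _, s2 = sysid.czt_spectrum(ts)
        after = np.angle(s2[sysid.grid_indices(freqs, [1.0])[0]])
        assert before == after


class TestAcrossFlies:
    def mk(self, gain, phase):
        return sysid.FrequencyResponse.from_gain_phase(
            np.array([1.0, 2.0]), np.array(gain), np.array(phase))

    def test_identical_inputs(self):
        fr = self.mk([1.0, 2.0], [10.0, -20.0])
        avg = sysid.average_across_flies([fr, fr, fr])
        assert np.allclose(avg.gain, [1.0, 2.0])
        assert np.allclose(avg.phase, [10.0, -20.0])
        assert np.allclose(avg.gain_sd, 0.0)
        assert np.allclose(avg.phase_sd_circ, 0.0, atol=1e-4)
        assert avg.n_flies == 3

    def test_circular_phase_mean_wraps(self):
        a = self.mk([1.0, 1.0], [179.0, 0.0])
        b = self.mk([1.0, 1.0], [-179.0, 0.0])
        avg = sysid.average_across_flies([a, b])
        assert np.isclose(avg.phase[0], 180.0)

    def test_gain_statistics(self):
        a = self.mk([1.0, 1.0], [0.0, 0.0])
        b = self.mk([3.0, 3.0], [0.0, 0.0])
        avg = sysid.average_across_flies([a, b])
        assert np.isclose(avg.gain[0], 2.0)
        assert np.isclose(avg.gain_sd[0], np.sqrt(2.0))

    def test_mismatched_grids_rejected(self):
        a = self.mk([1.0, 1.0], [0.0, 0.0])
        b = sysid.FrequencyResponse.from_gain_phase(
            np.array([1.0, 3.0]), np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="grid"):
            sysid.average_across_flies([a, b])


class TestPropagateUncertainty:
    def mk(self, gain, gain_sd=0.0, phase_sd=0.0):
        n = 3
        return sysid.FrequencyResponse.from_gain_phase(
            np.arange(1.0, n + 1), np.full(n, gain), np.zeros(n),
            gain_sd=np.full(n, gain_sd), phase_sd_circ=np.full(n, phase_sd))

    def test_zero_input_sd_gives_zero_output_sd(self):
        out = sysid.propagate_uncertainty(
            [self.mk(2.0), self.mk(0.5)], lambda a, b: a * b, n_draws=200)
        assert np.allclose(out.gain_sd, 0.0)
        assert np.allclose(out.gain, 1.0)

    def test_product_relative_sd_adds_in_quadrature(self):
        s1, s2 = 0.03, 0.04
        out = sysid.propagate_uncertainty(
            [self.mk(1.0, gain_sd=s1), self.mk(1.0, gain_sd=s2)],
            lambda a, b: a * b, n_draws=4000, seed=5)
        assert np.allclose(out.gain_sd, np.hypot(s1, s2), rtol=0.1)

    def test_seed_determinism(self):
        args = ([self.mk(1.0, 0.1, 5.0), self.mk(2.0, 0.2, 10.0)], "weighting")
        a = sysid.propagate_uncertainty(*args, n_draws=300, seed=3)
        b = sysid.propagate_uncertainty(*args, n_draws=300, seed=3)
        assert np.array_equal(a.gain_sd, b.gain_sd)
        assert np.array_equal(a.phase_sd_circ, b.phase_sd_circ)

    def test_rejects_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            sysid.propagate_uncertainty([self.mk(1.0)], "mechano_only",
                                        n_draws=10)
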