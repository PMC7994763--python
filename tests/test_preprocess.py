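import numpy as np
import pytest
from scipy.special import sph_harm_y

from conftest import build_trialset
from entrainlock.preprocess import (PreprocConfig, PreprocError,
                                    csd_matrices, csd_transform, downsample,
                                    ica_decay_suppression,
                                    interpolate_pulse_windows, preprocess,
                                    reject_trials, rereference_earlobes)
from entrainlock.protocol import StimProtocol, epoch_n_samples
from entrainlock.synth import NoiseConfig, simulate_trialset


class TestRereference:
    def test_direct_recomputation(self, tiny_trialset):
        out = rereference_earlobes(tiny_trialset)
        a1 = tiny_trialset.channel_index("A1")
        a2 = tiny_trialset.channel_index("A2")
        ref = (tiny_trialset.data[:, a1] + tiny_trialset.data[:, a2]) / 2
        for ch in out.channels:
            i_in = tiny_trialset.channel_index(ch)
            i_out = out.channel_index(ch)
            assert np.allclose(out.data[:, i_out],
                               tiny_trialset.data[:, i_in] - ref)
        assert "A1" not in out.channels and "A2" not in out.channels

    def test_zero_and_cancelling_references(self, tiny_trialset):
        ts = tiny_trialset
        for a1val, a2val in ((0.0, 0.0), (2.0, -2.0)):
            data = ts.data.copy()
            data[:, ts.channel_index("A1")] = a1val
            data[:, ts.channel_index("A2")] = a2val
            src = ts.copy_with(data=data)
            out = rereference_earlobes(src)
            scalp = [c for c in ts.channels if c not in ("A1", "A2")]
            idx = [ts.channel_index(c) for c in scalp]
            assert np.allclose(out.data, data[:, idx])

    def test_missing_earlobe_raises(self, tiny_trialset):
        ts = tiny_trialset
        keep = [i for i, c in enumerate(ts.channels) if c != "A2"]
        broken = ts.copy_with(data=ts.data[:, keep],
                              channels=[ts.channels[i] for i in keep])
        with pytest.raises(PreprocError, match="A2"):
            rereference_earlobes(broken)


class TestInterpolation:
    @pytest.mark.parametrize("interp_ms, n_replaced", [(8.0, 40), (12.0, 60)])
    def test_window_sample_counts_at_native_rate(self, montage63, interp_ms,
                                                 n_replaced):
        """8 ms -> 40 samples and 12 ms -> 60 samples at 5 kHz."""
        fs = 5000.0
        proto = StimProtocol(site="motor", n_pulses=2, train_freq_hz=5.0,
                             n_trials=1, epoch_pre_s=0.1, epoch_post_s=0.1)
        n = epoch_n_samples(proto, fs)
        rng = np.random.default_rng(0)
        data = rng.normal(size=(1, 2, n))
        ts = build_trialset(montage63, data, fs, proto,
                            channels=["C3", "Cz"])
        out = interpolate_pulse_windows(ts, PreprocConfig(
            interp_ms=interp_ms))
        changed = np.flatnonzero(out.data[0, 0] != data[0, 0])
        assert len(changed) == 2 * n_replaced   # two pulses
        s = ts.pulse_samples[0, 0]
        assert changed[0] == s + 1
        assert changed[n_replaced - 1] == s + n_replaced

    def test_linear_signal_is_fixed_point(self, montage63):
        fs = 1000.0
        proto = StimProtocol(site="motor", n_pulses=1, n_trials=1,
                             epoch_pre_s=0.1, epoch_post_s=0.1)
        n = epoch_n_samples(proto, fs)
        data = np.linspace(0, 1, n)[None, None, :] * np.ones((1, 2, 1))
        ts = build_trialset(montage63, data, fs, proto,
                            channels=["C3", "Cz"])
        out = interpolate_pulse_windows(ts, PreprocConfig())
        assert np.allclose(out.data, data, atol=1e-12)

    def test_overlapping_windows_error_names_pulses(self, montage63):
        fs = 1000.0
        proto = StimProtocol(site="motor", n_pulses=2, train_freq_hz=200.0,
                             n_trials=1, epoch_pre_s=0.1, epoch_post_s=0.1)
        n = epoch_n_samples(proto, fs)
        ts = build_trialset(montage63, np.zeros((1, 2, n)), fs, proto,
                            channels=["C3", "Cz"])
        with pytest.raises(PreprocError, match="pulses 1 and 2"):
            interpolate_pulse_windows(ts, PreprocConfig(interp_ms=8.0))


def _laplace_noise_trialset(montage, seed, n_ch=8, n_trials=10, n_t=500,
                            fs=500.0):
    proto = StimProtocol(site="motor", n_pulses=1, n_trials=n_trials,
                         epoch_pre_s=0.2, epoch_post_s=n_t / fs - 0.2)
    rng = np.random.default_rng(seed)
    data = rng.laplace(0, 2.0, size=(n_trials, n_ch, n_t))
    pulses = np.full((n_trials, 1), int(0.2 * fs))
    chans = ["C3", "C4", "Cz", "Fz", "Pz", "Oz", "O2", "POz"][:n_ch]
    return build_trialset(montage, data, fs, proto, channels=chans,
                          pulse_samples=pulses)


class TestICA:
    def test_injected_decay_pattern_removed(self, montage63):
        """A 20x decay artifact on one spatial pattern is identified and
        its post-pulse energy suppressed by >90%."""
        ts = _laplace_noise_trialset(montage63, seed=1)
        fs, s = ts.fs_hz, ts.pulse_samples[0, 0]
        t = np.arange(ts.n_times - s) / fs
        kern = 40.0 * np.exp(-t / 0.02)
        pattern = np.array([1.0, -0.5, 0.3, 0.8, -0.2, 0.1, 0.4, -0.6])
        dirty = ts.data.copy()
        dirty[:, :, s:] += pattern[None, :, None] * kern[None, None, :]
        ts_dirty = ts.copy_with(data=dirty)
        clean, report = ica_decay_suppression(ts_dirty, PreprocConfig(),
                                              seed=0)
        assert report["removed"].any()
        win = slice(s, s + int(0.008 * fs) + 1)
        resid = clean.data[:, :, win] - ts.data[:, :, win]
        before = dirty[:, :, win] - ts.data[:, :, win]
        assert (resid**2).sum() < 0.1 * (before**2).sum()

    def test_infinite_threshold_is_roundtrip(self, montage63):
        ts = _laplace_noise_trialset(montage63, seed=2)
        cfg = PreprocConfig(ica_z_thresh=np.inf)
        clean, report = ica_decay_suppression(ts, cfg, seed=0)
        assert not report["removed"].any()
        assert np.allclose(clean.data, ts.data, atol=1e-8)

    def test_false_positive_rate_on_stationary_noise(self, montage63):
        """With no pulse-locked structure the max-z rule removes well under
        30% of components (Monte-Carlo over seeds)."""
        rates = []
        for seed in range(20):
            ts = _laplace_noise_trialset(montage63, seed=100 + seed)
            _, report = ica_decay_suppression(ts, PreprocConfig(),
                                              seed=seed)
            rates.append(report["removed"].mean())
        assert np.mean(rates) < 0.30


class TestRejection:
    def _ts(self, montage, data, fs=500.0):
        proto = StimProtocol(site="motor", n_pulses=2, train_freq_hz=5.0,
                             n_trials=data.shape[0], epoch_pre_s=2.0,
                             epoch_post_s=3.0)
        return build_trialset(montage, data, fs, proto,
                              channels=["C3", "Cz"])

    def test_zero_data_keeps_everything(self, montage63):
        n = epoch_n_samples(StimProtocol(n_pulses=2, train_freq_hz=5.0,
                                         n_trials=3), 500.0)
        ts = self._ts(montage63, np.zeros((3, 2, n)))
        out, report = reject_trials(ts, PreprocConfig())
        assert out.n_trials == 3
        assert report["kept"].all()

    def test_excursion_inside_window_drops_exactly_that_trial(self,
                                                              montage63):
        n = epoch_n_samples(StimProtocol(n_pulses=2, train_freq_hz=5.0,
                                         n_trials=3), 500.0)
        data = np.zeros((3, 2, n))
        last = int(2.2 * 500)                      # last pulse sample
        data[1, 0, last + 250] = 250.0             # +0.5 s: inside window
        ts = self._ts(montage63, data)
        out, report = reject_trials(ts, PreprocConfig())
        assert out.n_trials == 2
        assert report.loc[1, "kept"] == False  # noqa: E712
        assert out.protocol.n_trials == 2

    def test_excursion_outside_window_is_ignored(self, montage63):
        n = epoch_n_samples(StimProtocol(n_pulses=2, train_freq_hz=5.0,
                                         n_trials=3), 500.0)
        data = np.zeros((3, 2, n))
        last = int(2.2 * 500)
        data[1, 0, last + 2 * 500] = 300.0         # +2 s: outside window
        ts = self._ts(montage63, data)
        out, _ = reject_trials(ts, PreprocConfig())
        assert out.n_trials == 3

    def test_all_rejected_raises(self, montage63):
        n = epoch_n_samples(StimProtocol(n_pulses=2, train_freq_hz=5.0,
                                         n_trials=2), 500.0)
        ts = self._ts(montage63, np.full((2, 2, n), 300.0))
        with pytest.raises(PreprocError):
            reject_trials(ts, PreprocConfig())

    def test_survival_rate_matches_excursion_probability(self, montage63):
        """Excursions injected with p=1/6 per trial leave about 25 of 30."""
        kept = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = epoch_n_samples(StimProtocol(n_pulses=2, train_freq_hz=5.0,
                                             n_trials=30), 500.0)
            data = np.zeros((30, 2, n))
            hit = rng.random(30) < 1 / 6
            data[hit, 0, int(2.0 * 500)] = 250.0
            ts = self._ts(montage63, data)
            out, _ = reject_trials(ts, PreprocConfig())
            kept.append(out.n_trials)
        assert 23 <= np.mean(kept) <= 27


class TestCSD:
    def _scalp_ts(self, montage, data, fs=500.0):
        proto = StimProtocol(site="motor", n_pulses=1,
                             n_trials=data.shape[0], epoch_pre_s=0.01,
                             epoch_post_s=data.shape[2] / fs - 0.01)
        pulses = np.full((data.shape[0], 1), 5, dtype=np.int64)
        return build_trialset(montage, data, fs, proto,
                              channels=montage.scalp_labels,
                              pulse_samples=pulses)

    def test_constant_field_annihilated(self, montage63):
        ts = self._scalp_ts(montage63, np.full((1, 63, 50), 7.5))
        out = csd_transform(ts, PreprocConfig())
        assert np.abs(out.data).max() < 1e-8
        assert out.units == "uV/m2"

    def test_reference_invariance(self, montage63):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(2, 63, 30))
        a = csd_transform(self._scalp_ts(montage63, data), PreprocConfig())
        b = csd_transform(self._scalp_ts(montage63, data + 11.0),
                          PreprocConfig())
        assert np.allclose(a.data, b.data, atol=1e-8)

    @pytest.mark.parametrize("degree", [2, 3])
    def test_spherical_harmonic_closed_form(self, montage63, degree):
        """The surface Laplacian of a sectoral harmonic Y_l^l is
        l(l+1) Y_l^l / R^2; the spline estimate must track the closed form
        (harmonic axis chosen within the sensed upper hemisphere)."""
        pos = montage63.positions[:63]
        theta = np.arccos(pos[:, 2])
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        y = sph_harm_y(degree, degree, theta, phi).real
        op = csd_matrices(pos)
        est = op @ y
        closed = degree * (degree + 1) * y
        r = np.corrcoef(est, closed)[0, 1]
        assert r > 0.99

    def test_too_few_channels_error(self, montage63):
        proto = StimProtocol(site="motor", n_pulses=1, n_trials=1,
                             epoch_pre_s=0.01, epoch_post_s=0.05)
        ts = build_trialset(montage63, np.zeros((1, 2, 30)), 500.0, proto,
                            channels=["C3", "Cz"],
                            pulse_samples=np.array([[5]]))
        with pytest.raises(PreprocError, match="32"):
            csd_transform(ts, PreprocConfig())


class TestDownsample:
    def _ts(self, montage, data, fs):
        proto = StimProtocol(site="motor", n_pulses=1, n_trials=1,
                             epoch_pre_s=2.0,
                             epoch_post_s=data.shape[2] / fs - 2.0)
        return build_trialset(montage, data, fs, proto,
                              channels=["C3", "Cz"])

    def test_sinusoid_amplitude_preserved(self, montage63):
        fs = 5000.0
        t = np.arange(int(4 * fs)) / fs
        sig = np.cos(2 * np.pi * 11.0 * t)
        data = np.tile(sig, (1, 2, 1))
        ts = self._ts(montage63, data, fs)
        out = downsample(ts, PreprocConfig(target_fs_hz=1000.0))
        spec_in = np.abs(np.fft.rfft(sig)) / len(sig)
        spec_out = np.abs(np.fft.rfft(out.data[0, 0])) / out.data.shape[-1]
        f_in = np.fft.rfftfreq(len(sig), 1 / fs)
        f_out = np.fft.rfftfreq(out.data.shape[-1], 1 / 1000.0)
        a_in = spec_in[np.argmin(np.abs(f_in - 11.0))]
        a_out = spec_out[np.argmin(np.abs(f_out - 11.0))]
        assert 0.99 <= a_out / a_in <= 1.01
        assert out.fs_hz == 1000.0

    def test_pulse_indices_rescaled_and_length(self, montage63):
        fs = 5000.0
        data = np.random.default_rng(0).normal(size=(1, 2, 25000))
        ts = self._ts(montage63, data, fs)
        ts = ts.copy_with(pulse_samples=np.array([[10000]]))
        out = downsample(ts, PreprocConfig(target_fs_hz=1000.0))
        assert out.pulse_samples[0, 0] == 2000
        assert abs(out.n_times - 25000 // 5) <= 1

    def test_non_integer_ratio_errors(self, montage63):
        data = np.zeros((1, 2, 6000))
        ts = self._ts(montage63, data, 1500.0)
        with pytest.raises(PreprocError, match="integer"):
            downsample(ts, PreprocConfig(target_fs_hz=400.0))


def test_pipeline_order_enforced(montage63):
    proto = StimProtocol(site="visual", n_pulses=2, train_freq_hz=11.0,
                         n_trials=4)
    ts = simulate_trialset(proto, montage=montage63, fs_hz=500.0, seed=9,
                           noise=NoiseConfig(evoked_amp_uv=0.0))
    cfg = PreprocConfig(target_fs_hz=500.0, run_ica=False)
    out, report = preprocess(ts, cfg, seed=0)
    assert report["stages"] == ["rereference_earlobes",
                                "interpolate_pulse_windows",
                                "reject_trials", "csd_transform",
                                "downsample"]
    assert out.units == "uV/m2"
    assert len(out.channels) == 63
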