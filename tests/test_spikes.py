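import numpy as np
import pytest
from hypothesis import given, strategies as st

import wismux as wm
from wismux import reference_data as ref
from wismux.scenes import _render_spikes
from wismux.spikes import SnippetSet


def _stream(x, f_s=30e3):
    return wm.ChannelStream(1, x, f_s)


def _sine(f0, f_s=30e3, duration=1.0, amp=1.0):
    t = np.arange(int(duration * f_s)) / f_s
    return amp * np.sin(2 * np.pi * f0 * t)


def _amp(x, f0=None, f_s=30e3):
    mid = slice(x.size // 4, 3 * x.size // 4)  # avoid edge transients
    if f0 is None:
        return (x[mid].max() - x[mid].min()) / 2
    # least-squares sine fit is insensitive to slow filtfilt transients
    t = np.arange(x.size)[mid] / f_s
    basis = np.column_stack([np.sin(2 * np.pi * f0 * t),
                             np.cos(2 * np.pi * f0 * t), np.ones_like(t)])
    coef = np.linalg.lstsq(basis, x[mid], rcond=None)[0]
    return float(np.hypot(coef[0], coef[1]))


class TestFilters:
    def test_raw_filter_passband_at_100_hz(self):
        y = wm.raw_filter(_stream(_sine(100.0, duration=4.0))).samples
        assert _amp(y, f0=100.0) == pytest.approx(1.0, rel=0.02)

    def test_raw_filter_rejects_10_khz(self):
        y = wm.raw_filter(_stream(_sine(10e3))).samples
        assert _amp(y) <= 10 ** (-12 / 20)  # >= 12 dB down

    def test_raw_filter_removes_dc(self):
        y = wm.raw_filter(_stream(np.ones(30000))).samples
        assert np.abs(y[10000:20000]).max() < 1e-2

    def test_spike_filter_passband_at_2_khz(self):
        y = wm.spike_filter(_stream(_sine(2e3))).samples
        assert _amp(y) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("f0", [0.0, 60.0])
    def test_spike_filter_rejects_dc_and_mains(self, f0):
        x = np.ones(30000) if f0 == 0 else _sine(f0)
        y = wm.spike_filter(_stream(x)).samples
        assert np.abs(y[10000:20000]).max() <= 10 ** (-40 / 20)

    def test_spike_filter_zero_phase_preserves_symmetry(self):
        x = np.zeros(30000)
        c = 15000
        x[c - 30:c + 31] = np.hanning(61)
        y = wm.spike_filter(_stream(x)).samples
        assert y[c - 200:c] == pytest.approx(y[c + 200:c:-1], abs=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            wm.spike_filter(_stream(np.zeros(1000), f_s=6e3))


class TestDetection:
    def test_zero_stream_yields_no_events(self):
        with pytest.warns(UserWarning):
            snips = wm.detect_crossings(_stream(np.zeros(3000)))
        assert snips.n_events == 0

    def test_recall_on_injected_templates_in_low_noise(self):
        """Templates placed at known times are all recovered with trough
        alignment within 0.2 ms."""
        f_s = 30e3
        rng = np.random.default_rng(0)
        truth = np.arange(0.1, 1.9, 0.25)
        cfg = wm.SpikeSceneConfig(amplitude_pkpk_v=16e-6)
        x = _render_spikes(truth, cfg, int(2.0 * f_s), f_s)
        x += 0.5e-6 * rng.standard_normal(x.size)
        snips = wm.detect_crossings(wm.spike_filter(_stream(x)))
        det = snips.trough_times()
        matched = [np.any(np.abs(det - t) <= 0.2e-3) for t in truth]
        assert np.mean(matched) >= 0.95
        assert snips.n_events == truth.size

    def test_noise_event_rate_close_to_direct_crossing_count(self):
        """On pure Gaussian noise the detector rate is within 2x of the
        sample-wise threshold-crossing count (dead time explains the gap)."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300000) * 1e-6
        stream = _stream(x)
        snips = wm.detect_crossings(stream, k=3.0)
        thr = snips.threshold_v
        below = x < thr
        direct = np.sum(below[1:] & ~below[:-1])
        assert direct > 0
        assert direct / 2 <= max(snips.n_events, 1) <= direct * 2

    def test_dead_time_one_snippet(self):
        snips = wm.detect_crossings(_stream(
            np.random.default_rng(2).standard_normal(60000)))
        if snips.n_events > 1:
            assert np.diff(snips.times).min() >= 48 / 30e3 - 1e-12

    def test_events_strictly_increasing_invariant(self):
        rng = np.random.default_rng(3)
        snips = wm.detect_crossings(_stream(rng.standard_normal(30000)))
        assert np.all(np.diff(snips.times) > 0)


class TestHoops:
    def _mixture(self, seed, n_true=50, n_art=12):
        rng = np.random.default_rng(seed)
        _, w = wm.default_template(f_grid=30e3)
        tpl = w * 16e-6
        true = tpl + 1e-6 * rng.standard_normal((n_true, tpl.size))
        art = -tpl + 1e-6 * rng.standard_normal((n_art, tpl.size))
        wf = np.vstack([true, art])
        times = np.arange(wf.shape[0]) * 0.01
        snips = SnippetSet(1, times, wf, 30e3, -1.0, 1.0, 16)
        return snips, tpl, n_true, n_art

    def test_template_itself_accepted(self):
        snips, tpl, n_true, _ = self._mixture(0)
        kept = wm.hoop_isolate(snips, tpl)
        # all template-like events are within the hoops
        assert kept.n_events >= n_true * 0.95

    def test_gross_trough_outlier_rejected(self):
        snips, tpl, _, _ = self._mixture(1)
        sd_t = np.std(snips.waveforms, axis=0)
        trough = int(np.argmin(tpl))
        bad = tpl.copy()
        bad[trough] += 10 * 1.7 * sd_t[trough]
        wf = np.vstack([snips.waveforms, bad])
        times = np.append(snips.times, snips.times[-1] + 0.01)
        grown = SnippetSet(1, times, wf, 30e3, -1.0, 1.0, 16)
        kept = wm.hoop_isolate(grown, tpl)
        assert kept.n_events < grown.n_events
        assert not np.any([np.array_equal(r, bad) for r in kept.waveforms])

    @pytest.mark.parametrize("seed", range(20))
    def test_inverted_artifacts_rejected(self, seed):
        """Amplitude-inverted artifacts mixed with template events are
        rejected at >= 90%."""
        snips, tpl, n_true, n_art = self._mixture(seed)
        kept = wm.hoop_isolate(snips, tpl)
        survivors = np.sum(kept.waveforms[:, int(np.argmin(tpl))] > 0)
        assert survivors <= 0.1 * n_art

    def test_too_few_events_pass_through(self):
        _, w = wm.default_template(f_grid=30e3)
        snips = SnippetSet(1, np.array([0.0]), w[None, :] * 1e-6, 30e3,
                           -1.0, 1.0, 16)
        with pytest.warns(UserWarning):
            out = wm.hoop_isolate(snips, w * 1e-6)
        assert out.n_events == 1


class TestWaveformSnr:
    @pytest.mark.parametrize("pkpk_uv,sd_uv,expected", [
        (15.12, 2.90, 2.61),
        (17.11, 3.19, 2.68),
        (14.90, 2.59, 2.88),
    ])
    def test_published_slice_allocation_rows(self, pkpk_uv, sd_uv, expected):
        """The mean-waveform SNR statistic reproduces the published
        per-row values to two decimals."""
        _, w = wm.default_template(f_grid=30e3)
        wbar = w * pkpk_uv * 1e-6
        d = np.full_like(wbar, sd_uv * 1e-6)
        snips = SnippetSet(1, np.array([0.0, 0.1]),
                           np.vstack([wbar + d, wbar - d]), 30e3, -1.0, 1.0, 16)
        rep = wm.mean_waveform_snr(snips)
        assert round(rep.snr, 2) == expected
        assert rep.pkpk == pytest.approx(pkpk_uv * 1e-6, rel=1e-9)
        assert rep.sd_resid == pytest.approx(sd_uv * 1e-6, rel=1e-9)

    def test_flat_identical_snippets_give_zero(self):
        wf = np.zeros((3, 48))
        snips = SnippetSet(1, np.array([0.0, 0.1, 0.2]), wf, 30e3, -1.0, 1.0, 16)
        assert wm.mean_waveform_snr(snips).snr == 0.0

    def test_identical_structured_snippets_flagged_undefined(self):
        _, w = wm.default_template(f_grid=30e3)
        wf = np.vstack([w, w])
        snips = SnippetSet(1, np.array([0.0, 0.1]), wf, 30e3, -1.0, 1.0, 16)
        assert wm.mean_waveform_snr(snips).snr is None

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        wf = rng.standard_normal((10, 48))
        snips = SnippetSet(1, np.arange(10) * 0.01, wf, 30e3, -1.0, 1.0, 16)
        scaled = SnippetSet(1, snips.times, wf * scale, 30e3, -1.0, 1.0, 16)
        assert wm.mean_waveform_snr(scaled).snr == pytest.approx(
            wm.mean_waveform_snr(snips).snr, rel=1e-9)


class TestNoiseFloorAndIsi:
    def test_floor_without_events_is_whole_stream_rms(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30000)
        empty = SnippetSet(1, np.empty(0), np.empty((0, 48)), 30e3, -1.0, 1.0, 16)
        assert wm.noise_floor(_stream(x), empty) == pytest.approx(
            np.sqrt(np.mean(x ** 2)))

    def test_floor_recovers_known_sigma_with_sparse_events(self):
        """Excising sparse event windows leaves the true noise sigma within 3%."""
        sigma = 2e-6
        floors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = sigma * rng.standard_normal(30000)
            times = np.arange(0.05, 0.95, 0.1)
            wf = np.zeros((times.size, 48))
            snips = SnippetSet(1, times, wf, 30e3, -1.0, 1.0, 16)
            floors.append(wm.noise_floor(_stream(x), snips))
        assert np.mean(floors) == pytest.approx(sigma, rel=0.03)

    def test_zero_stream_floor_is_zero(self):
        empty = SnippetSet(1, np.empty(0), np.empty((0, 48)), 30e3, -1.0, 1.0, 16)
        assert wm.noise_floor(_stream(np.zeros(1000)), empty) == 0.0

    def test_isi_trivial_cases(self):
        one = SnippetSet(1, np.array([0.5]), np.zeros((1, 48)), 30e3, -1, 1, 16)
        assert wm.isi_intervals(one).size == 0
        times = np.arange(0, 1.0, 0.1)
        reg = SnippetSet(1, times, np.zeros((times.size, 48)), 30e3, -1, 1, 16)
        assert wm.isi_intervals(reg) == pytest.approx(np.full(9, 0.1))

    def test_bursting_defaults_put_half_the_isi_mass_below_20_ms(self):
        """Within-burst firing dominates the interval distribution."""
        fracs = []
        for seed in range(10):
            t = wm.gen_spike_train(wm.SpikeSceneConfig(), 60.0, seed=seed)
            isi = np.diff(t)
            fracs.append(np.mean(isi < 20e-3))
        assert np.mean(fracs) > 0.5

    def test_isi_histogram_shape(self):
        counts, edges = wm.isi_histogram([0.005, 0.015, 0.5], bin_s=1e-3,
                                         max_s=0.1)
        assert counts.sum() == 2  # 0.5 s falls outside the 100 ms range
        assert edges.size == counts.size + 1


class TestSummary:
    def test_published_column_means(self):
        """Channel summary reproduces the published column averages of the
        10-electrode comparison (chip pk-pk 15.62 uV; bench SNR 3.07)."""
        t = ref.spike_comparison_table()
        reports = {int(r.channel): wm.WaveformReport(
            pkpk=r.chip_pkpk_uv * 1e-6, sd_resid=0.0, snr=r.bench_snr,
            n_events=100) for r in t.itertuples()}
        floors = {int(r.channel): r.chip_floor_uvrms * 1e-6
                  for r in t.itertuples()}
        offsets = {int(r.channel): r.offset_mv * 1e-3 for r in t.itertuples()}
        table = wm.summarize_channels(reports, floors, offsets)
        mean = table[table.electrode == "mean"].iloc[0]
        assert round(mean.pkpk_uv, 2) == 15.62
        assert round(mean.snr, 2) == 3.07

    def test_empty_input_gives_empty_table(self):
        assert wm.summarize_channels({}, {}, {}).empty
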