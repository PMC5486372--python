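"""Detector stages: baseline, threshold, candidates, the three validations,
and whole-channel properties (determinism, scale invariance, monotonicity)."""

import numpy as np
import pytest

import megripple.detector as det
from megripple.detector import (
    BaselineMask,
    DetectorConfig,
    RippleEvent,
    compute_channel_threshold,
    detect_baseline,
    detect_channel,
    find_candidates,
    validate_amplitude,
    validate_entropy_stability,
    validate_psd,
)
from megripple.recording import GroundTruthAnnotation
from megripple.stockwell import EntropyTrace
from megripple.synthetic import generate_background, inject_event, simulate_recording

FS = 1250.0


def _mask_all(n, baseline=True):
    return BaselineMask(
        n_samples=n,
        epoch_spans=[(0, n)],
        is_baseline=np.full(n, baseline),
        is_sampled=np.ones(n, dtype=bool),
    )


class TestDetectBaseline:
    def test_white_noise_is_mostly_baseline(self, detector_config):
        rec = generate_background(1, 60.0, FS, spectral_exponent=0.0, seed=21)
        mask = detect_baseline(rec.data[:, 0], FS, detector_config, rng=1)
        assert mask.baseline_fraction >= 0.90
        assert len(mask.epoch_spans) == 120

    def test_sustained_oscillation_excluded(self, detector_config):
        rec = generate_background(1, 20.0, FS, 1.0, seed=22)
        x = rec.data[:, 0].copy()
        t = np.arange(x.size) / FS
        osc = slice(int(9.0 * FS), int(11.0 * FS))
        x[osc] += 10.0 * np.sin(2 * np.pi * 120.0 * t[osc])
        mask = detect_baseline(x, FS, detector_config, rng=2)
        inside = mask.is_baseline[osc][mask.is_sampled[osc]]
        outside_sel = mask.is_sampled.copy()
        outside_sel[osc] = False
        outside = mask.is_baseline[outside_sel]
        assert inside.size > 0  # oscillation region was sampled
        assert inside.mean() < 0.3
        assert outside.mean() > 0.9

    def test_entropy_exactly_at_threshold_is_not_baseline(
        self, detector_config, monkeypatch
    ):
        """Strict inequality: a trace pinned at 0.85*H_max yields no baseline."""

        def constant_entropy(x, fs, band):
            h_max = np.log(461)
            return EntropyTrace(
                values=np.full(x.size, 0.85 * h_max), h_max=h_max
            )

        monkeypatch.setattr(det, "_epoch_entropy", constant_entropy)
        rec = generate_background(1, 5.0, FS, 0.0, seed=0)
        mask = detect_baseline(rec.data[:, 0], FS, detector_config, rng=0)
        assert mask.baseline_indices.size == 0
        with pytest.raises(ValueError, match="baseline"):
            compute_channel_threshold(rec.data[:, 0], mask, detector_config)

    def test_record_shorter_than_epoch_rejected(self, detector_config):
        with pytest.raises(ValueError):
            detect_baseline(np.zeros(100), FS, detector_config, rng=0)

    def test_seed_determinism(self, detector_config):
        rec = generate_background(1, 10.0, FS, 1.0, seed=5)
        a = detect_baseline(rec.data[:, 0], FS, detector_config, rng=7)
        b = detect_baseline(rec.data[:, 0], FS, detector_config, rng=7)
        assert a.epoch_spans == b.epoch_spans
        np.testing.assert_array_equal(a.is_baseline, b.is_baseline)


class TestChannelThreshold:
    def test_nearest_rank_convention(self, detector_config):
        envelope = np.arange(1.0, 101.0)  # values 1..100
        thr = compute_channel_threshold(
            envelope, _mask_all(100), detector_config, envelope=envelope
        )
        assert thr == 98.0  # ceil(0.98 * 100) = 98th order statistic

    def test_constant_envelope(self, detector_config):
        envelope = np.full(200, 7.5)
        thr = compute_channel_threshold(
            envelope, _mask_all(200), detector_config, envelope=envelope
        )
        assert thr == 7.5

    def test_positive_homogeneity(self, detector_config):
        rng = np.random.default_rng(8)
        envelope = rng.rayleigh(size=500)
        m = _mask_all(500)
        a = compute_channel_threshold(envelope, m, detector_config, envelope=envelope)
        b = compute_channel_threshold(
            2.0 * envelope, m, detector_config, envelope=2.0 * envelope
        )
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_too_few_baseline_samples_rejected(self, detector_config):
        envelope = np.ones(40)
        with pytest.raises(ValueError):
            compute_channel_threshold(
                envelope, _mask_all(40), detector_config, envelope=envelope
            )


class TestFindCandidates:
    def _env(self, spans, n=2000, high=2.0):
        env = np.full(n, 0.5)
        for s, e in spans:
            env[s:e] = high
        return env

    def test_exactly_20ms_run_is_detected(self, detector_config):
        env = self._env([(100, 125)])  # 25 samples = 20.0 ms at 1250 Hz
        cands = find_candidates(env, 1.0, FS, detector_config, envelope=env)
        assert cands == [(100, 125)]

    def test_just_below_20ms_rejected(self, detector_config):
        env = self._env([(100, 124)])  # 24 samples = 19.2 ms
        assert find_candidates(env, 1.0, FS, detector_config, envelope=env) == []

    def test_short_gap_merged_before_duration_test(self, detector_config):
        # two 15-sample runs, 5-sample (4 ms) gap -> one 35-sample candidate
        env = self._env([(100, 115), (120, 135)])
        cands = find_candidates(env, 1.0, FS, detector_config, envelope=env)
        assert cands == [(100, 135)]

    def test_long_gap_not_merged(self, detector_config):
        env = self._env([(100, 130), (200, 230)])
        cands = find_candidates(env, 1.0, FS, detector_config, envelope=env)
        assert cands == [(100, 130), (200, 230)]

    def test_no_overlap_after_merging(self, detector_config):
        rng = np.random.default_rng(12)
        env = rng.rayleigh(size=20_000)
        cands = find_candidates(env, 1.5, FS, detector_config, envelope=env)
        for (s1, e1), (s2, e2) in zip(cands, cands[1:]):
            assert e1 <= s2

    def test_nonpositive_threshold_rejected(self, detector_config):
        with pytest.raises(ValueError):
            find_candidates(np.ones(100), 0.0, FS, detector_config)


class TestEntropyStability:
    def _event(self, n):
        return RippleEvent(channel=0, start=0, end=n, fs=FS)

    def test_ratio_below_125_accepted(self, detector_config):
        ev = self._event(4)
        trace = EntropyTrace(values=np.array([5.0, 1.0, 1.2, 5.0]), h_max=6.0)
        assert validate_entropy_stability(ev, trace, detector_config) is True

    def test_ratio_exactly_125_rejected_strict(self, detector_config):
        ev = self._event(4)
        trace = EntropyTrace(values=np.array([5.0, 1.0, 1.25, 5.0]), h_max=6.0)
        assert validate_entropy_stability(ev, trace, detector_config) is False

    def test_endpoints_excluded(self, detector_config):
        ev = self._event(4)
        trace = EntropyTrace(values=np.array([9.9, 1.0, 1.1, 9.9]), h_max=10.0)
        assert validate_entropy_stability(ev, trace, detector_config) is True

    def test_no_interior_fails_with_reason(self, detector_config):
        ev = self._event(2)
        trace = EntropyTrace(values=np.array([1.0, 1.0]), h_max=2.0)
        assert validate_entropy_stability(ev, trace, detector_config) is False
        assert ev.reject_reason == "no interior"


class TestAmplitude:
    def _channel_with_event(self, peak, flank_pattern, n_flank=1000, start=2000):
        # flanks alternate 3/7: mean(|x|) = 5, SD = 2
        x = np.tile(flank_pattern, 3 * n_flank)[: start + 30 + n_flank].astype(float)
        x[start : start + 30] = 0.0
        x[start + 15] = peak
        return x, RippleEvent(channel=0, start=start, end=start + 30, fs=FS)

    def _mean_cfg(self):
        return DetectorConfig(amplitude_mode="mean-flank")

    def test_mean_flank_arithmetic_accept(self):
        x, ev = self._channel_with_event(10.0, [3.0, 7.0])
        assert validate_amplitude(ev, x, self._mean_cfg()) is True  # 10 > 5 + 2

    def test_mean_flank_arithmetic_reject(self):
        x, ev = self._channel_with_event(6.9, [3.0, 7.0])
        assert validate_amplitude(ev, x, self._mean_cfg()) is False  # 6.9 < 7

    def test_left_flank_truncated_at_record_edge(self):
        x, _ = self._channel_with_event(10.0, [3.0, 7.0], start=2000)
        ev = RippleEvent(channel=0, start=300, end=330, fs=FS)
        x2 = x.copy()
        x2[300:330] = 0.0
        x2[315] = 10.0
        assert validate_amplitude(ev, x2, self._mean_cfg()) is True

    def test_insufficient_context_rejected_with_reason(self, detector_config):
        x, _ = self._channel_with_event(10.0, [3.0, 7.0])
        ev = RippleEvent(channel=0, start=100, end=130, fs=FS)
        assert validate_amplitude(ev, x, detector_config) is False
        assert ev.reject_reason == "insufficient context"

    def test_peak_flank_default_requires_clearing_flank_peaks(self, detector_config):
        # peak 7.5 clears mean+SD (7) but not flank max + SD (7 + 2) -> reject
        x, ev = self._channel_with_event(7.5, [3.0, 7.0])
        assert validate_amplitude(ev, x, detector_config) is False
        x2, ev2 = self._channel_with_event(10.0, [3.0, 7.0])
        assert validate_amplitude(ev2, x2, detector_config) is True


class TestPsd:
    def test_injected_ripple_trough_then_peak(self, detector_config):
        rec = generate_background(1, 6.0, FS, 1.0, seed=31)
        ann = GroundTruthAnnotation(
            kind="ripple", channel=0, onset_s=3.0, duration_s=0.06,
            amplitude=5.0, center_frequency_hz=100.0,
        )
        rec, _ = inject_event(rec, ann)
        s, e = ann.sample_span(FS)
        ev = RippleEvent(channel=0, start=s, end=e, fs=FS)
        assert validate_psd(ev, rec.data[:, 0], FS, detector_config) is True
        assert ev.psd_trough_hz < ev.psd_peak_hz
        assert 40.0 < ev.psd_peak_hz <= 250.0

    def test_spike_transients_mostly_rejected(self, detector_config):
        """Sharp broadband transients lack a distinct in-band spectral peak."""
        rejected = 0
        for seed in range(8):
            rec = generate_background(1, 6.0, FS, 1.0, seed=100 + seed)
            ann = GroundTruthAnnotation(
                kind="spike", channel=0, onset_s=3.0, duration_s=0.04, amplitude=6.0
            )
            rec, _ = inject_event(rec, ann)
            s, e = ann.sample_span(FS)
            ev = RippleEvent(channel=0, start=s, end=e, fs=FS)
            rejected += not validate_psd(ev, rec.data[:, 0], FS, detector_config)
        assert rejected >= 6

    def test_peak_below_40hz_does_not_count(self, detector_config):
        rng = np.random.default_rng(33)
        t = np.arange(int(6 * FS)) / FS
        x = 0.01 * rng.standard_normal(t.size)
        burst = slice(int(3.0 * FS), int(3.06 * FS))
        x[burst] += np.sin(2 * np.pi * 30.0 * t[burst])
        ev = RippleEvent(channel=0, start=burst.start, end=burst.stop, fs=FS)
        assert validate_psd(ev, x, FS, detector_config) is False

    def test_segment_too_short_fails_with_reason(self, detector_config):
        cfg = DetectorConfig(event_pad_s=0.0)
        cfg._bandpass_cache = detector_config._bandpass_cache
        ev = RippleEvent(channel=0, start=100, end=130, fs=FS)
        x = np.random.default_rng(0).standard_normal(5000)
        assert validate_psd(ev, x, FS, cfg) is False
        assert "PSD" in ev.reject_reason


@pytest.fixture(scope="module")
def small_world(detector_config):
    rec, anns = simulate_recording(
        n_channels=1, duration_s=20.0, n_ripples=3, seed=77, channels=[0]
    )
    res = detect_channel(rec.data[:, 0], FS, detector_config, rng=5, channel=0)
    return rec, anns, res


class TestDetectChannel:
    def test_recovers_injected_ripples(self, small_world):
        rec, anns, res = small_world
        hits = 0
        for a in anns:
            t0, t1 = a.onset_s, a.onset_s + a.duration_s
            m = [ev for ev in res.events if ev.start_s < t1 and t0 < ev.end_s]
            if m:
                hits += 1
                assert min(abs(ev.start_s - t0) for ev in m) <= 0.010
        assert hits >= 2

    def test_accepted_events_satisfy_all_criteria(self, small_world):
        _, _, res = small_world
        for ev in res.events:
            assert ev.stability_ok and ev.amplitude_ok and ev.psd_ok
        for ev in res.candidates:
            assert ev.accepted == ev.all_criteria()

    def test_determinism_and_scale_invariance(self, detector_config, small_world):
        rec, _, res = small_world
        again = detect_channel(rec.data[:, 0], FS, detector_config, rng=5, channel=0)
        assert [(e.start, e.end) for e in again.events] == [
            (e.start, e.end) for e in res.events
        ]
        scaled = detect_channel(
            7.0 * rec.data[:, 0], FS, detector_config, rng=5, channel=0
        )
        assert [(e.start, e.end) for e in scaled.events] == [
            (e.start, e.end) for e in res.events
        ]
        assert [(e.stability_ok, e.amplitude_ok, e.psd_ok) for e in scaled.candidates] == [
            (e.stability_ok, e.amplitude_ok, e.psd_ok) for e in res.candidates
        ]

    def test_monotonic_in_percentile_and_duration(self, detector_config, small_world):
        """Raising the envelope percentile or the minimum duration never
        increases the number of candidates."""
        rec, _, _ = small_world
        from megripple.filters import apply_zero_phase_array
        from megripple.detector import hilbert_envelope

        x = rec.data[:, 0]
        filt = apply_zero_phase_array(detector_config.bandpass(FS), x)
        env = hilbert_envelope(filt)
        mask = detect_baseline(x, FS, detector_config, rng=5)
        counts_pct = []
        for pct in (90.0, 95.0, 98.0, 99.5):
            cfg = DetectorConfig(cdf_percentile=pct)
            thr = compute_channel_threshold(filt, mask, cfg, env)
            counts_pct.append(len(find_candidates(filt, thr, FS, cfg, env)))
        assert counts_pct == sorted(counts_pct, reverse=True)
        counts_dur = []
        thr = compute_channel_threshold(filt, mask, detector_config, env)
        for dur in (10.0, 20.0, 40.0, 80.0):
            cfg = DetectorConfig(min_duration_ms=dur)
            counts_dur.append(len(find_candidates(filt, thr, FS, cfg, env)))
        assert counts_dur == sorted(counts_dur, reverse=True)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(entropy_threshold_frac=1.5)
        with pytest.raises(ValueError):
            DetectorConfig(cdf_percentile=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(stability_ratio=1.0)
        with pytest.raises(ValueError):
            DetectorConfig(amplitude_mode="bogus")

    def test_yaml_round_trip(self, tmp_path):
        cfg = DetectorConfig(cdf_percentile=95.0, merge_gap_ms=12.0)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        restored = DetectorConfig.from_yaml(path)
        assert restored.cdf_percentile == 95.0
        assert restored.merge_gap_ms == 12.0
        assert restored.psd_band == cfg.psd_band
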