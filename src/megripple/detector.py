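"""Automatic ripple detection on individual channels.

Two-step algorithm per channel:

1. *Baseline identification.* The Stockwell entropy is computed for 120
   randomly placed one-second epochs; samples whose entropy exceeds
   0.85 x the maximum entropy are baseline (noise-like spectrum). The entropy
   is computed on the broadband (unfiltered) trace — see the methods note.
2. *Event detection.* The channel is band-pass filtered (elliptic, 70–253 Hz
   at -3 dB); the Hilbert envelope over all baseline samples forms a CDF whose
   98th percentile is the channel threshold. Envelope excursions above the
   threshold lasting at least 20 ms are candidate ripples.

A candidate is a true ripple only if it passes three validations:

(a) entropy stability — over the event interior (first/last sample excluded)
    max entropy < 125% of min entropy;
(b) amplitude — peak |filtered| inside the event exceeds mean + 1 SD of
    |filtered| over 1000-sample flanks on each side;
(c) spectral peak — the PSD of the (unfiltered) event segment shows a local
    peak above 40 Hz (and at or below 250 Hz) preceded by a trough at a lower
    frequency.

All comparisons are strict, all criteria are relative (the detector is
invariant to positive rescaling of the channel), and sample intervals are
0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .filters import FilterSpec, design_ripple_bandpass, apply_zero_phase_array
from .stockwell import EntropyTrace, stockwell_entropy, stockwell_transform

__all__ = [
    "DetectorConfig",
    "BaselineMask",
    "RippleEvent",
    "DetectionResult",
    "detect_baseline",
    "compute_channel_threshold",
    "find_candidates",
    "validate_entropy_stability",
    "validate_amplitude",
    "validate_psd",
    "detect_channel",
    "detect_recording",
]


@dataclass
class DetectorConfig:
    """Every numeric threshold of the detector in one place.

    Defaults reproduce the published MEG-adapted detector: 70–253 Hz elliptic
    band-pass (60 dB stopband, 0.5 dB passband), 120 random 1 s baseline
    epochs, entropy threshold 0.85 x max entropy, 98th-percentile envelope
    threshold, 20 ms minimum duration, 125% entropy-stability bound,
    1000-sample / 1 SD amplitude flanks, and the 40–250 Hz PSD band.
    """

    # band-pass front end
    bp_f_low: float = 70.0
    bp_f_high: float = 253.0
    bp_passband_ripple_db: float = 0.5
    bp_stopband_atten_db: float = 60.0
    bp_stopband_edges: tuple[float, float] = (55.0, 290.0)
    # baseline stage
    baseline_n_epochs: int = 120
    baseline_epoch_s: float = 1.0
    entropy_threshold_frac: float = 0.85
    entropy_band: tuple[float, float] = (40.0, 500.0)
    entropy_max_mode: str = "theoretical"  # or "empirical"
    # candidate stage
    cdf_percentile: float = 98.0
    min_duration_ms: float = 20.0
    merge_gap_ms: float = 10.0
    # validation (a): entropy stability. The entropy trace for this criterion
    # is computed on the band-passed trace over the ripple band with a long
    # (0.5 s) context pad: the fine frequency resolution keeps the per-sample
    # entropy of a steady narrow-band burst flat, which is what the criterion
    # is meant to measure (see methods note).
    stability_ratio: float = 1.25
    stability_signal: str = "filtered"  # or "raw"
    stability_band: tuple[float, float] = (80.0, 250.0)
    stability_pad_s: float = 0.5
    event_pad_s: float = 0.1
    # validation (b): amplitude vs flanks. "Absolute amplitude" of a flank is
    # read as its peak |x| (the clinical meaning of the amplitude of a signal
    # stretch); a mean-based reading is available as "mean-flank".
    flank_samples: int = 1000
    flank_sd_multiplier: float = 1.0
    flank_min_samples: int = 250
    amplitude_mode: str = "peak-flank"  # or "mean-flank" | "pooled"
    # validation (c): PSD peak/trough. The PSD is estimated from the
    # S-transform (mean power over the event samples), which is smooth in
    # frequency like the published spectra; a raw periodogram mode exists.
    psd_band: tuple[float, float] = (40.0, 250.0)
    psd_peak_min_hz: float = 40.0
    psd_estimator: str = "stockwell"  # or "periodogram"
    psd_f_min_hz: float = 10.0  # transform floor: troughs live below the peak
    psd_f_max_hz: float = 300.0
    psd_smooth_bins: int = 5  # periodogram mode only
    # chance bumps of 1/f background on the S-transform PSD reach ~8 dB over
    # event-length windows; genuine ripples stand >= 15 dB above their trough
    psd_prominence_db: float = 8.0

    _bandpass_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.entropy_threshold_frac < 1.0):
            raise ValueError("entropy_threshold_frac must be in (0, 1)")
        if not (0.0 < self.cdf_percentile < 100.0):
            raise ValueError("cdf_percentile must be in (0, 100)")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be positive")
        if self.stability_ratio <= 1.0:
            raise ValueError("stability_ratio must exceed 1")
        if self.entropy_max_mode not in ("theoretical", "empirical"):
            raise ValueError("entropy_max_mode must be 'theoretical' or 'empirical'")
        if self.amplitude_mode not in ("peak-flank", "mean-flank", "pooled"):
            raise ValueError(
                "amplitude_mode must be 'peak-flank', 'mean-flank' or 'pooled'"
            )
        if self.stability_signal not in ("filtered", "raw"):
            raise ValueError("stability_signal must be 'filtered' or 'raw'")
        if self.psd_estimator not in ("stockwell", "periodogram"):
            raise ValueError("psd_estimator must be 'stockwell' or 'periodogram'")

    def bandpass(self, fs: float) -> FilterSpec:
        """Design (and cache) the ripple band-pass for a sampling rate."""
        key = float(fs)
        if key not in self._bandpass_cache:
            self._bandpass_cache[key] = design_ripple_bandpass(
                fs=fs,
                f_low=self.bp_f_low,
                f_high=self.bp_f_high,
                passband_ripple_db=self.bp_passband_ripple_db,
                stopband_atten_db=self.bp_stopband_atten_db,
                stopband_edges=self.bp_stopband_edges,
            )
        return self._bandpass_cache[key]

    def min_duration_samples(self, fs: float) -> int:
        return int(round(self.min_duration_ms * fs / 1000.0))

    def entropy_band_capped(self, fs: float) -> tuple[float, float]:
        return (self.entropy_band[0], min(self.entropy_band[1], fs / 2.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_bandpass_cache", None)
        d["bp_stopband_edges"] = list(self.bp_stopband_edges)
        d["entropy_band"] = list(self.entropy_band)
        d["psd_band"] = list(self.psd_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        for k in ("bp_stopband_edges", "entropy_band", "psd_band"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class BaselineMask:
    """Per-sample baseline classification over the sampled epochs."""

    n_samples: int
    epoch_spans: list[tuple[int, int]]
    is_baseline: np.ndarray  # bool, full record length; False outside epochs
    is_sampled: np.ndarray  # bool, True inside any sampled epoch
    channel: Optional[int] = None

    @property
    def baseline_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_baseline)

    @property
    def baseline_fraction(self) -> float:
        """Fraction of sampled-epoch samples classified as baseline."""
        n_sampled = int(self.is_sampled.sum())
        return float(self.is_baseline.sum() / n_sampled) if n_sampled else 0.0


@dataclass
class RippleEvent:
    """One candidate/detected event on one channel (half-open sample span)."""

    channel: int
    start: int
    end: int
    fs: float
    peak_envelope: float = np.nan
    entropy_min: float = np.nan
    entropy_max: float = np.nan
    flank_level_left: float = np.nan
    flank_level_right: float = np.nan
    peak_abs_amplitude: float = np.nan
    psd_trough_hz: float = np.nan
    psd_peak_hz: float = np.nan
    stability_ok: bool = False
    amplitude_ok: bool = False
    psd_ok: bool = False
    reject_reason: str = ""
    accepted: bool = False

    @property
    def start_s(self) -> float:
        return self.start / self.fs

    @property
    def end_s(self) -> float:
        return self.end / self.fs

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def all_criteria(self) -> bool:
        return self.stability_ok and self.amplitude_ok and self.psd_ok


@dataclass
class DetectionResult:
    """Accepted events plus a full audit trail for one channel."""

    channel: int
    events: list[RippleEvent]  # passing all three criteria
    candidates: list[RippleEvent]  # every supra-threshold candidate, flagged
    threshold: float
    baseline: BaselineMask


def _epoch_entropy(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> EntropyTrace:
    tf = stockwell_transform(x, fs, band[0], band[1])
    return stockwell_entropy(tf)


def detect_baseline(
    channel_signal: np.ndarray,
    fs: float,
    config: DetectorConfig,
    rng: Union[int, np.random.Generator, None] = 0,
) -> BaselineMask:
    """Identify baseline samples from randomly placed 1 s entropy epochs.

    Epoch starts are drawn uniformly without replacement from all valid start
    samples. A sample inside a sampled epoch is baseline if its Stockwell
    entropy is strictly greater than ``entropy_threshold_frac`` x the maximum
    entropy (theoretical ln(n_freq_bins) by default).
    """
    x = np.asarray(channel_signal, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("channel contains non-finite values")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    epoch_len = int(round(config.baseline_epoch_s * fs))
    n = x.size
    if n < epoch_len:
        raise ValueError(
            f"record ({n} samples) shorter than one baseline epoch ({epoch_len})"
        )
    n_valid = n - epoch_len + 1
    n_epochs = min(config.baseline_n_epochs, n_valid)
    starts = np.sort(rng.choice(n_valid, size=n_epochs, replace=False))
    band = config.entropy_band_capped(fs)

    traces: list[np.ndarray] = []
    h_maxes: list[float] = []
    emp_max = 0.0
    for s0 in starts:
        trace = _epoch_entropy(x[s0 : s0 + epoch_len], fs, band)
        traces.append(trace.values)
        h_maxes.append(trace.h_max)
        emp_max = max(emp_max, float(trace.values.max()))

    is_baseline = np.zeros(n, dtype=bool)
    is_sampled = np.zeros(n, dtype=bool)
    spans: list[tuple[int, int]] = []
    for s0, values, h_max in zip(starts, traces, h_maxes):
        ref = emp_max if config.entropy_max_mode == "empirical" else h_max
        thresh = config.entropy_threshold_frac * ref
        span = slice(int(s0), int(s0) + epoch_len)
        is_sampled[span] = True
        is_baseline[span] |= values > thresh  # strict
        spans.append((int(s0), int(s0) + epoch_len))
    return BaselineMask(
        n_samples=n, epoch_spans=spans, is_baseline=is_baseline, is_sampled=is_sampled
    )


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(np.asarray(x, dtype=float)))


def compute_channel_threshold(
    filtered_channel: np.ndarray,
    baseline_mask: BaselineMask,
    config: DetectorConfig,
    envelope: Optional[np.ndarray] = None,
) -> float:
    """Channel threshold: nearest-rank 98th percentile of the Hilbert-envelope
    CDF over all baseline samples of the band-passed signal."""
    if envelope is None:
        envelope = hilbert_envelope(filtered_channel)
    values = envelope[baseline_mask.baseline_indices]
    if values.size == 0:
        raise ValueError("empty baseline: review the entropy threshold")
    if values.size < 50:
        raise ValueError(
            f"only {values.size} baseline samples (< 50): threshold unreliable"
        )
    ordered = np.sort(values)
    k = int(np.ceil(config.cdf_percentile / 100.0 * ordered.size))
    return float(ordered[k - 1])


def find_candidates(
    filtered_channel: np.ndarray,
    threshold: float,
    fs: float,
    config: DetectorConfig,
    envelope: Optional[np.ndarray] = None,
) -> list[tuple[int, int]]:
    """Supra-threshold envelope runs: merge near-adjacent runs (gap strictly
    below ``merge_gap_ms``), then keep runs lasting at least
    ``min_duration_ms``. Returns half-open (start, end) spans."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if envelope is None:
        envelope = hilbert_envelope(filtered_channel)
    above = envelope > threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    # merge runs separated by short gaps, before the duration test
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        gap_ms = (s - merged[-1][1]) / fs * 1000.0
        if gap_ms < config.merge_gap_ms:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    min_len = config.min_duration_samples(fs)
    return [(s, e) for s, e in merged if e - s >= min_len]


def event_entropy_trace(
    event_span: tuple[int, int],
    channel_signal: np.ndarray,
    fs: float,
    config: DetectorConfig,
) -> EntropyTrace:
    """Stockwell entropy over the event span for the stability criterion.

    Recomputed on the event segment padded by ``stability_pad_s`` on each side
    (padding trimmed afterwards), over ``stability_band``. Pass the band-passed
    trace when ``config.stability_signal == 'filtered'`` (the default)."""
    start, end = event_span
    x = np.asarray(channel_signal, dtype=float)
    pad = int(round(config.stability_pad_s * fs))
    lo = max(0, start - pad)
    hi = min(x.size, end + pad)
    band = (config.stability_band[0], min(config.stability_band[1], fs / 2.0))
    trace = _epoch_entropy(x[lo:hi], fs, band)
    return EntropyTrace(values=trace.values[start - lo : end - lo], h_max=trace.h_max)


def validate_entropy_stability(
    event: RippleEvent, entropy_trace: EntropyTrace, config: DetectorConfig
) -> bool:
    """Criterion (a): over the event interior (first and last sample excluded)
    max entropy strictly below ``stability_ratio`` x min entropy."""
    values = entropy_trace.values
    if values.size != event.n_samples:
        raise ValueError("entropy trace length must equal event length")
    if values.size < 3:
        event.stability_ok = False
        event.reject_reason = "no interior"
        return False
    interior = values[1:-1]
    event.entropy_min = float(interior.min())
    event.entropy_max = float(interior.max())
    event.stability_ok = bool(event.entropy_max < config.stability_ratio * event.entropy_min)
    return event.stability_ok


def validate_amplitude(
    event: RippleEvent, filtered_channel: np.ndarray, config: DetectorConfig
) -> bool:
    """Criterion (b): peak |filtered| inside the event strictly exceeds the
    flank amplitude + k*SD(|x|) of the 1000-sample flanks, each flank
    separately (flanks truncated at record edges, >= ``flank_min_samples``).

    The flank amplitude is its peak |x| in the default "peak-flank" mode,
    or mean(|x|) in "mean-flank" / "pooled" modes."""
    x = np.asarray(filtered_channel, dtype=float)
    left = np.abs(x[max(0, event.start - config.flank_samples) : event.start])
    right = np.abs(x[event.end : event.end + config.flank_samples])
    if left.size < config.flank_min_samples or right.size < config.flank_min_samples:
        event.amplitude_ok = False
        event.reject_reason = "insufficient context"
        return False
    peak = float(np.max(np.abs(x[event.start : event.end])))
    event.peak_abs_amplitude = peak
    k = config.flank_sd_multiplier
    if config.amplitude_mode == "pooled":
        pooled = np.concatenate([left, right])
        level = float(pooled.mean() + k * pooled.std())
        event.flank_level_left = event.flank_level_right = level
        event.amplitude_ok = bool(peak > level)
    else:
        amp = np.max if config.amplitude_mode == "peak-flank" else np.mean
        lvl_l = float(amp(left) + k * left.std())
        lvl_r = float(amp(right) + k * right.std())
        event.flank_level_left, event.flank_level_right = lvl_l, lvl_r
        event.amplitude_ok = bool(peak > lvl_l and peak > lvl_r)
    return event.amplitude_ok


def validate_psd(
    event: RippleEvent,
    unfiltered_channel: np.ndarray,
    fs: float,
    config: DetectorConfig,
) -> bool:
    """Criterion (c): the PSD of the padded, mean-removed event segment has a
    distinct local peak in (40, 250] Hz (prominence >= ``psd_prominence_db``),
    preceded by a local trough at a lower frequency.

    In the default "stockwell" mode the PSD is the S-transform power averaged
    over the event samples; in "periodogram" mode a smoothed periodogram of
    the whole padded segment is used."""
    x = np.asarray(unfiltered_channel, dtype=float)
    pad = int(round(config.event_pad_s * fs))
    lo = max(0, event.start - pad)
    hi = min(x.size, event.end + pad)
    segment = x[lo:hi]
    if segment.size < int(round(0.08 * fs)):
        event.psd_ok = False
        event.reject_reason = "segment too short for PSD"
        return False
    f_lo = config.psd_f_min_hz
    f_hi = min(config.psd_f_max_hz, fs / 2.0)
    if config.psd_estimator == "stockwell":
        seg = segment - segment.mean()
        tf = stockwell_transform(seg, fs, f_lo, f_hi)
        psd = tf.power[:, event.start - lo : event.end - lo].mean(axis=1)
        freqs = tf.freqs_hz
    else:
        freqs, psd = sps.periodogram(segment, fs=fs, detrend="constant")
        keep = (freqs >= f_lo) & (freqs <= f_hi)
        freqs, psd = freqs[keep], psd[keep]
        if config.psd_smooth_bins > 1:
            kernel = np.ones(config.psd_smooth_bins) / config.psd_smooth_bins
            psd = np.convolve(psd, kernel, mode="same")
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(np.maximum(psd, 1e-300))
    peaks, _ = sps.find_peaks(psd_db, prominence=config.psd_prominence_db)
    troughs, _ = sps.find_peaks(-psd_db)
    in_band = peaks[
        (freqs[peaks] > config.psd_peak_min_hz) & (freqs[peaks] <= config.psd_band[1])
    ]
    event.psd_ok = False
    for p in in_band:
        lower_troughs = troughs[troughs < p]
        if lower_troughs.size:
            event.psd_peak_hz = float(freqs[p])
            event.psd_trough_hz = float(freqs[lower_troughs[-1]])
            event.psd_ok = True
            break
    return event.psd_ok


def detect_channel(
    raw_channel: np.ndarray,
    fs: float,
    config: Optional[DetectorConfig] = None,
    rng: Union[int, np.random.Generator, None] = 0,
    channel: int = 0,
) -> DetectionResult:
    """Full per-channel pipeline: band-pass, baseline, threshold, candidates,
    three validations. Returns accepted events plus the audited candidates."""
    config = config or DetectorConfig()
    x = np.asarray(raw_channel, dtype=float)
    bp = config.bandpass(fs)
    filtered = apply_zero_phase_array(bp, x)
    baseline = detect_baseline(x, fs, config, rng)
    baseline.channel = channel
    envelope = hilbert_envelope(filtered)
    threshold = compute_channel_threshold(filtered, baseline, config, envelope)
    spans = find_candidates(filtered, threshold, fs, config, envelope)
    candidates: list[RippleEvent] = []
    for start, end in spans:
        ev = RippleEvent(channel=channel, start=start, end=end, fs=fs)
        ev.peak_envelope = float(envelope[start:end].max())
        stab_sig = filtered if config.stability_signal == "filtered" else x
        trace = event_entropy_trace((start, end), stab_sig, fs, config)
        validate_entropy_stability(ev, trace, config)
        validate_amplitude(ev, filtered, config)
        validate_psd(ev, x, fs, config)
        ev.accepted = ev.all_criteria()
        candidates.append(ev)
    accepted = [ev for ev in candidates if ev.accepted]
    return DetectionResult(
        channel=channel,
        events=accepted,
        candidates=candidates,
        threshold=threshold,
        baseline=baseline,
    )


def detect_recording(
    recording,
    config: Optional[DetectorConfig] = None,
    seed: int = 0,
) -> list[DetectionResult]:
    """Run the detector on every channel of a recording.

    Each channel gets an independent random stream spawned from ``seed`` so
    results do not depend on channel processing order.
    """
    config = config or DetectorConfig()
    seq = np.random.SeedSequence(seed)
    streams = seq.spawn(recording.n_channels)
    results = []
    for ch in range(recording.n_channels):
        rng = np.random.default_rng(streams[ch])
        results.append(
            detect_channel(recording.channel(ch), recording.fs, config, rng, channel=ch)
        )
    return results


def events_to_frame(results: Sequence[DetectionResult], accepted_only: bool = True):
    """Flatten detection results into a DataFrame (CSV-ready schema)."""
    import pandas as pd

    rows = []
    for res in results:
        pool = res.events if accepted_only else res.candidates
        for ev in pool:
            rows.append(
                {
                    "channel": ev.channel,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                    "peak_env": ev.peak_envelope,
                    "H_min": ev.entropy_min,
                    "H_max": ev.entropy_max,
                    "psd_trough_Hz": ev.psd_trough_hz,
                    "psd_peak_Hz": ev.psd_peak_hz,
                    "stability_ok": ev.stability_ok,
                    "amplitude_ok": ev.amplitude_ok,
                    "psd_ok": ev.psd_ok,
                    "accepted": ev.accepted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "start_s",
            "end_s",
            "peak_env",
            "H_min",
            "H_max",
            "psd_trough_Hz",
            "psd_peak_Hz",
            "stability_ok",
            "amplitude_ok",
            "psd_ok",
            "accepted",
        ],
    )
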