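"""Seeded synthetic MEG-like signals with exact ground truth.

Real interictal MEG cannot ship with a test suite, so every downstream stage is
exercised on simulated recordings: spectrally shaped 1/f^alpha Gaussian
background, plus three injected event archetypes —

* ripple: a Tukey-windowed sinusoid (default 100–140 Hz, 40–80 ms), the
  band-limited burst the detector is built to find;
* spike: a sharp biphasic difference-of-Gaussians transient (20–70 ms, dominant
  energy below 30 Hz with a broadband edge) — the classic confounder, since
  band-pass filtering a sharp transient produces ripple-like ringing;
* emg: a broadband 60–300 Hz noise burst (>= 200 ms) mimicking muscle artifact.

All event amplitudes are expressed as unitless multiples of the local
background RMS (ripple: ripple-band RMS; spike/emg: broadband RMS), so tests
are scale-free. Every generator is a pure function of its arguments including
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .recording import (
    GroundTruthAnnotation,
    MultichannelRecording,
    validate_annotation_fits,
)

__all__ = [
    "SyntheticLeadfield",
    "generate_background",
    "inject_event",
    "generate_leadfield",
    "simulate_recording",
    "ripple_band_rms",
]

RIPPLE_BAND = (80.0, 250.0)


@dataclass
class SyntheticLeadfield:
    """Forward gains mapping a dipole at each source to the sensor array."""

    gain: np.ndarray  # (n_channels, n_sources, 3)
    source_positions: np.ndarray  # (n_sources, 3)
    seed: int

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must have shape (n_channels, n_sources, 3)")
        if not np.isfinite(self.gain).all():
            raise ValueError("gain contains non-finite entries")
        for s in range(self.n_sources):
            if np.linalg.matrix_rank(self.gain[:, s, :]) < 2:
                raise ValueError(f"per-source gain rank < 2 for source {s}")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_background(
    n_channels: int,
    duration_s: float,
    fs: float = 1250.0,
    spectral_exponent: float = 1.0,
    rms: float = 1.0,
    seed: Union[int, np.random.Generator, None] = 0,
) -> MultichannelRecording:
    """1/f^alpha Gaussian background noise, seeded and reproducible.

    White Gaussian noise is shaped in the frequency domain by |f|^(-alpha/2)
    (zero DC) and each channel rescaled to exactly the requested RMS.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    if duration_s < 2.0:
        raise ValueError("duration must be at least 2 s")
    if not (0.0 <= spectral_exponent <= 2.0):
        raise ValueError("spectral_exponent must lie in [0, 2]")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal((n, n_channels))
    spectrum = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spectral_exponent / 2.0)
    data = np.fft.irfft(spectrum * shaping[:, None], n=n, axis=0)
    scale = rms / np.sqrt(np.mean(data**2, axis=0))
    data *= scale[None, :]
    return MultichannelRecording(data=data, fs=fs)


def ripple_band_rms(
    x: np.ndarray, fs: float, band: tuple[float, float] = RIPPLE_BAND
) -> float:
    """RMS of a 1-D segment restricted to a frequency band (4th-order
    Butterworth, zero phase)."""
    x = np.asarray(x, dtype=float)
    sos = sps.butter(4, band, btype="bandpass", output="sos", fs=fs)
    padlen = min(x.size - 1, 3 * (sos.shape[0] + 1) * 2 * 5)
    filtered = sps.sosfiltfilt(sos, x, padlen=padlen)
    return float(np.sqrt(np.mean(filtered**2)))


def _ripple_waveform(
    n: int, fs: float, freq_hz: float, window_shape: str, taper: float = 0.25
) -> np.ndarray:
    t = np.arange(n) / fs
    carrier = np.sin(2.0 * np.pi * freq_hz * t)
    if window_shape == "tukey":
        win = sps.windows.tukey(n, alpha=taper)
    elif window_shape == "gaussian":
        win = sps.windows.gaussian(n, std=n / 6.0)
    else:
        raise ValueError(f"unknown window shape {window_shape!r}")
    return carrier * win


def _spike_waveform(n: int) -> np.ndarray:
    """Sharp biphasic spike transient, peak magnitude 1.

    Difference of Gaussians (dominant energy well below 30 Hz for 20-70 ms
    durations) plus a small exponential cusp at the apex. The cusp gives the
    broadband 1/f^2 spectral edge of a sharp transient — in-band energy that
    rings the ripple band-pass — without introducing any spectral peak above
    40 Hz, which is exactly what makes spikes a confounder for detectors."""
    t = np.linspace(-1.0, 1.0, n)
    narrow = np.exp(-(t**2) / (2 * 0.30**2))
    wide = np.exp(-((t - 0.35) ** 2) / (2 * 0.55**2))
    cusp = np.exp(-np.abs(t) / 0.02)
    w = narrow - 0.55 * wide + 0.35 * cusp
    return w / np.max(np.abs(w))


def _emg_waveform(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    hi = min(300.0, 0.45 * fs)
    sos = sps.butter(4, [60.0, hi], btype="bandpass", output="sos", fs=fs)
    burst = sps.sosfiltfilt(sos, noise, padlen=min(n - 1, 120))
    return burst * sps.windows.tukey(n, alpha=0.25)


def inject_event(
    recording: MultichannelRecording,
    annotation: GroundTruthAnnotation,
    window_shape: str = "tukey",
    rng: Union[int, np.random.Generator, None] = 0,
) -> tuple[MultichannelRecording, GroundTruthAnnotation]:
    """Add one annotated event to a recording (the input is not modified).

    The event is purely additive and confined to the annotated span.
    Scaling conventions:

    * ripple — the event's ripple-band RMS over its span equals
      ``amplitude`` x the local (pre-injection) ripple-band RMS of that span;
    * spike — peak |amplitude| equals ``amplitude`` x local broadband RMS;
    * emg — burst RMS equals ``amplitude`` x local broadband RMS.
    """
    validate_annotation_fits(annotation, recording)
    fs = recording.fs
    start, end = annotation.sample_span(fs)
    n = end - start
    if n < 2:
        raise ValueError("event span must cover at least 2 samples")
    out = recording.copy()
    segment = recording.data[start:end, annotation.channel]

    if annotation.kind == "ripple":
        if annotation.center_frequency_hz is None:
            raise ValueError("ripple annotation requires center_frequency_hz")
        wave = _ripple_waveform(n, fs, annotation.center_frequency_hz, window_shape)
        local = ripple_band_rms(segment, fs)
        wave_rms = np.sqrt(np.mean(wave**2))
        scale = annotation.amplitude * local / wave_rms if wave_rms > 0 else 0.0
    elif annotation.kind == "spike":
        if not (0.02 <= annotation.duration_s <= 0.07):
            raise ValueError("spike duration must lie in [20, 70] ms")
        wave = _spike_waveform(n)
        local = float(np.sqrt(np.mean(segment**2)))
        scale = annotation.amplitude * local
    elif annotation.kind == "emg":
        if annotation.duration_s < 0.2:
            raise ValueError("emg burst must last at least 200 ms")
        wave = _emg_waveform(n, fs, _as_rng(rng))
        local = float(np.sqrt(np.mean(segment**2)))
        wave_rms = np.sqrt(np.mean(wave**2))
        scale = annotation.amplitude * local / wave_rms if wave_rms > 0 else 0.0
    else:  # pragma: no cover - guarded by the annotation type
        raise ValueError(f"unknown event kind {annotation.kind!r}")

    out.data[start:end, annotation.channel] = segment + scale * wave
    return out, annotation


def generate_leadfield(
    n_channels: int,
    n_sources: int,
    seed: Union[int, np.random.Generator, None] = 0,
) -> SyntheticLeadfield:
    """Smooth seeded forward gains with well-conditioned per-source columns.

    Each source's (n_channels x 3) gain is built from smooth random channel
    profiles (low-order random Fourier series over the channel index),
    orthonormalized and given fixed singular values (1, 0.6, 0.3) so the
    orientation search is always well posed.
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels (orientation underdetermined)")
    if n_sources < 1:
        raise ValueError("need at least one source")
    rng = _as_rng(seed)
    seed_val = 0 if isinstance(seed, np.random.Generator) else int(seed or 0)
    c = np.arange(n_channels)
    gain = np.empty((n_channels, n_sources, 3))
    for s in range(n_sources):
        profiles = np.zeros((n_channels, 3))
        for col in range(3):
            coeffs = rng.standard_normal(4)
            phases = rng.uniform(0, 2 * np.pi, 4)
            for order in range(1, 5):
                profiles[:, col] += coeffs[order - 1] * np.cos(
                    2 * np.pi * order * c / n_channels + phases[order - 1]
                )
        q, _ = np.linalg.qr(profiles)
        rot = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        gain[:, s, :] = q @ np.diag([1.0, 0.6, 0.3]) @ rot
    positions = rng.uniform(-1.0, 1.0, (n_sources, 3))
    positions /= np.maximum(1.0, np.linalg.norm(positions, axis=1, keepdims=True))
    return SyntheticLeadfield(gain=gain, source_positions=positions, seed=seed_val)


def simulate_recording(
    n_channels: int = 8,
    duration_s: float = 60.0,
    fs: float = 1250.0,
    n_ripples: int = 5,
    n_spikes: int = 0,
    n_emg: int = 0,
    seed: int = 0,
    spectral_exponent: float = 1.0,
    ripple_amplitude: float = 5.0,
    spike_amplitude: float = 6.0,
    emg_amplitude: float = 3.0,
    ripple_freq_range: tuple[float, float] = (100.0, 140.0),
    ripple_duration_range: tuple[float, float] = (0.040, 0.080),
    channels: Optional[Sequence[int]] = None,
) -> tuple[MultichannelRecording, list[GroundTruthAnnotation]]:
    """Background plus randomly placed, non-overlapping annotated events.

    Event onsets are spaced at least 1.5 s apart and kept at least 1.2 s from
    the record edges so each event has full flanks for validation.
    """
    rng = np.random.default_rng(seed)
    rec = generate_background(
        n_channels, duration_s, fs, spectral_exponent, rms=1.0, seed=rng
    )
    margin, spacing = 1.2, 1.5
    n_events = n_ripples + n_spikes + n_emg
    annotations: list[GroundTruthAnnotation] = []
    if n_events == 0:
        return rec, annotations
    lo, hi = margin, duration_s - margin
    if hi - lo < spacing * n_events:
        raise ValueError("recording too short for the requested event count")
    # evenly partition the usable span, jitter within each slot
    slot = (hi - lo) / n_events
    onsets = lo + slot * (np.arange(n_events) + rng.uniform(0.1, 0.6, n_events))
    order = rng.permutation(n_events)
    kinds = ["ripple"] * n_ripples + ["spike"] * n_spikes + ["emg"] * n_emg
    chan_pool = list(channels) if channels is not None else list(range(n_channels))
    for i, kind in enumerate(kinds):
        onset = float(onsets[order[i]])
        channel = int(rng.choice(chan_pool))
        if kind == "ripple":
            ann = GroundTruthAnnotation(
                kind="ripple",
                channel=channel,
                onset_s=onset,
                duration_s=float(rng.uniform(*ripple_duration_range)),
                amplitude=ripple_amplitude,
                center_frequency_hz=float(rng.uniform(*ripple_freq_range)),
            )
        elif kind == "spike":
            ann = GroundTruthAnnotation(
                kind="spike",
                channel=channel,
                onset_s=onset,
                duration_s=float(rng.uniform(0.025, 0.060)),
                amplitude=spike_amplitude,
            )
        else:
            ann = GroundTruthAnnotation(
                kind="emg",
                channel=channel,
                onset_s=onset,
                duration_s=float(rng.uniform(0.2, 0.4)),
                amplitude=emg_amplitude,
            )
        rec, ann = inject_event(rec, ann, rng=rng)
        annotations.append(ann)
    return rec, annotations
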