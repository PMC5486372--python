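"""Stockwell (S-) transform and Stockwell entropy.

The S-transform is a time-frequency representation with a frequency-dependent
Gaussian window (width proportional to 1/f). For a length-N discrete signal it
is computed efficiently in the frequency domain: for each frequency index n > 0

    S[n, j] = IDFT_m{ X[(m + n) mod N] * exp(-2 pi^2 m^2 / n^2) }[j]

where X is the DFT of the signal. The per-sample Stockwell entropy is the
Shannon entropy (natural log) of the normalized power distribution over
frequency bins at each time sample; noise-like spectra give entropy near the
theoretical maximum ln(n_freqs), while narrow-band events (ripples) depress it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TimeFrequencyMap",
    "EntropyTrace",
    "stockwell_transform",
    "stockwell_transform_direct",
    "stockwell_entropy",
]


@dataclass
class TimeFrequencyMap:
    """Complex S-transform coefficients on a (frequency, time) grid."""

    values: np.ndarray  # complex, (n_freqs, n_samples)
    freqs_hz: np.ndarray  # strictly increasing, in (0, fs/2]
    fs: float
    channel: Optional[int] = None
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_freqs, n_samples)")
        if self.freqs_hz.shape[0] != self.values.shape[0]:
            raise ValueError("freqs length must match first axis of values")
        if self.freqs_hz.size and (
            np.any(np.diff(self.freqs_hz) <= 0)
            or self.freqs_hz[0] <= 0
            or self.freqs_hz[-1] > self.fs / 2 + 1e-9
        ):
            raise ValueError("frequencies must be strictly increasing in (0, fs/2]")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def n_freqs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EntropyTrace:
    """Per-sample Stockwell entropy H(t) in nats, with its theoretical max."""

    values: np.ndarray
    h_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9) or np.any(self.values > self.h_max + 1e-9):
            raise ValueError("entropy outside [0, h_max]")


def _frequency_indices(n: int, fs: float, f_min: float, f_max: float) -> np.ndarray:
    """DFT bin indices of an epoch of length n whose frequencies lie in
    [f_min, f_max]."""
    df = fs / n
    k_lo = int(np.ceil(f_min / df - 1e-9))
    k_hi = int(np.floor(f_max / df + 1e-9))
    k_lo = max(k_lo, 1)  # DC excluded: the 1/f window is undefined at n = 0
    k_hi = min(k_hi, n // 2)
    if k_hi < k_lo:
        raise ValueError(
            f"no DFT frequencies in [{f_min}, {f_max}] Hz for n={n}, fs={fs}"
        )
    return np.arange(k_lo, k_hi + 1)


def stockwell_transform(
    x: np.ndarray,
    fs: float,
    f_min: float,
    f_max: float,
    channel: Optional[int] = None,
    start_sample: int = 0,
) -> TimeFrequencyMap:
    """Discrete S-transform of a 1-D signal over the band [f_min, f_max].

    Frequencies are sampled at the DFT resolution fs/N of the analysis epoch
    (a 1 s epoch at 1250 Hz gives 1 Hz bins). O(N log N) per frequency voice.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("signal must be 1-D with at least 8 samples")
    if not (0 < f_min < f_max <= fs / 2):
        raise ValueError("need 0 < f_min < f_max <= fs/2")
    n = x.size
    ks = _frequency_indices(n, fs, f_min, f_max)
    X = np.fft.fft(x)
    m = np.fft.fftfreq(n, d=1.0 / n)  # signed DFT index grid
    # all voices at once: shifted spectra windowed by the frequency-domain
    # Gaussian exp(-2 pi^2 m^2 / k^2), one inverse FFT per voice
    shift_idx = (np.arange(n)[None, :] + ks[:, None]) % n
    gauss = np.exp(-2.0 * np.pi**2 * m[None, :] ** 2 / ks[:, None] ** 2)
    S = np.fft.ifft(X[shift_idx] * gauss, axis=1)
    return TimeFrequencyMap(
        values=S,
        freqs_hz=ks * fs / n,
        fs=fs,
        channel=channel,
        start_sample=start_sample,
    )


def stockwell_transform_direct(
    x: np.ndarray, fs: float, f_min: float, f_max: float
) -> TimeFrequencyMap:
    """O(N^2) direct-summation S-transform (reference implementation).

    Evaluates the defining sums term by term — the DFT by explicit summation
    and, for each (frequency, time) pair, the windowed inverse sum — without
    FFTs. Intended as an independent oracle for small N.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    ks = _frequency_indices(n, fs, f_min, f_max)
    # DFT by direct summation
    j = np.arange(n)
    X = np.array([np.sum(x * np.exp(-2j * np.pi * kk * j / n)) for kk in j])
    m_signed = np.where(j <= n // 2, j, j - n).astype(float)
    S = np.empty((ks.size, n), dtype=complex)
    for row, k in enumerate(ks):
        for t in range(n):
            acc = 0.0 + 0.0j
            for mi in range(n):
                gauss = np.exp(-2.0 * np.pi**2 * m_signed[mi] ** 2 / k**2)
                acc += (
                    X[(mi + k) % n]
                    * gauss
                    * np.exp(2j * np.pi * m_signed[mi] * t / n)
                )
            S[row, t] = acc / n
    return TimeFrequencyMap(values=S, freqs_hz=ks * fs / n, fs=fs)


def stockwell_entropy(tf_map: TimeFrequencyMap) -> EntropyTrace:
    """Shannon entropy (nats) of the per-sample power distribution over
    frequency bins.

    Invariant to global amplitude scaling. An all-zero column carries no
    spectral information and is assigned the maximum entropy ln(n_freqs).
    """
    if tf_map.n_freqs < 2:
        raise ValueError("entropy needs at least 2 frequency bins")
    power = tf_map.power
    h_max = float(np.log(tf_map.n_freqs))
    totals = power.sum(axis=0)
    h = np.full(tf_map.n_samples, h_max)
    ok = totals > 0
    if np.any(ok):
        p = power[:, ok] / totals[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h[ok] = np.clip(-plogp.sum(axis=0), 0.0, h_max)
    return EntropyTrace(values=h, h_max=h_max)
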