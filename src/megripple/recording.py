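"""Multichannel time-series container and ground-truth annotations.

The recording container is deliberately minimal: a samples-by-channels float
array plus sampling rate and channel metadata. It is shared by the raw
(physical-sensor) stage, the beamformer virtual-sensor stage and the synthetic
generator, so every pipeline step speaks the same type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Canonical lobe vocabulary used for concordance bookkeeping.
HEMISPHERES = ("L", "R")
LOBES = ("frontal", "temporal", "parietal", "occipital", "central")
LOBE_VOCABULARY = frozenset(
    f"{h}-{l}" for h in HEMISPHERES for l in LOBES
) | {"unknown"}

EVENT_KINDS = ("ripple", "spike", "emg")


@dataclass
class MultichannelRecording:
    """A samples x channels time series with sampling rate and labels.

    Parameters
    ----------
    data
        Real array of shape ``(n_samples, n_channels)``; arbitrary amplitude
        units (the whole detector is scale-invariant).
    fs
        Sampling rate in Hz. The clinical recordings this pipeline targets are
        sampled at 1250 Hz.
    channel_labels
        Unique channel names, one per column.
    channel_lobe
        Optional lobe label per channel, drawn from :data:`LOBE_VOCABULARY`.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_lobe: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if not (np.isscalar(self.fs) or np.ndim(self.fs) == 0) or self.fs <= 0:
            raise ValueError("fs must be a positive scalar")
        self.fs = float(self.fs)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != self.n_channels:
            raise ValueError("channel labels must be unique")
        if self.channel_lobe is not None:
            if len(self.channel_lobe) != self.n_channels:
                raise ValueError("one lobe label per channel required")
            bad = set(self.channel_lobe) - LOBE_VOCABULARY
            if bad:
                raise ValueError(f"unknown lobe labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as a 1-D view."""
        return self.data[:, index]

    def copy(self) -> "MultichannelRecording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            channel_lobe=None if self.channel_lobe is None else list(self.channel_lobe),
        )


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """One injected event with exact location and scale.

    ``amplitude`` is a unitless multiple of the local background RMS (band-
    limited RMS for ripples, broadband RMS for spikes and EMG bursts), so the
    annotation remains meaningful under any global rescaling of the recording.
    """

    kind: str
    channel: int
    onset_s: float
    duration_s: float
    amplitude: float
    center_frequency_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def sample_span(self, fs: float) -> tuple[int, int]:
        """Half-open [start, end) sample span at sampling rate ``fs``."""
        start = int(round(self.onset_s * fs))
        end = start + int(round(self.duration_s * fs))
        return start, end


def validate_annotation_fits(
    annotation: GroundTruthAnnotation, recording: MultichannelRecording
) -> None:
    """Raise if an annotation does not fit inside the recording."""
    if not (0 <= annotation.channel < recording.n_channels):
        raise ValueError(
            f"channel {annotation.channel} out of range "
            f"[0, {recording.n_channels})"
        )
    start, end = annotation.sample_span(recording.fs)
    if end > recording.n_samples:
        raise ValueError("annotation extends past the end of the recording")


def annotations_to_frame(annotations: Sequence[GroundTruthAnnotation]):
    """Ground-truth table as a pandas DataFrame (CSV-ready schema)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "kind": a.kind,
                "channel": a.channel,
                "onset_s": a.onset_s,
                "duration_s": a.duration_s,
                "freq_hz": a.center_frequency_hz,
                "amplitude": a.amplitude,
            }
            for a in annotations
        ],
        columns=["kind", "channel", "onset_s", "duration_s", "freq_hz", "amplitude"],
    )
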