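"""HDF5/CSV persistence for recordings, leadfields, weights and TF maps.

The HDF5 recording container stores /data (samples x channels, float64),
/fs (scalar), /labels (UTF-8 strings) and, optionally, an /annotations table
with the ground-truth schema (kind, channel, onset_s, duration_s, freq_hz,
amplitude). EDF export is intentionally not provided here; the HDF5 container
is the interchange format of this package.
"""

from __future__ import annotations

from typing import Optional, Sequence

import h5py
import numpy as np

from .beamformer import BeamformerWeights
from .recording import GroundTruthAnnotation, MultichannelRecording
from .stockwell import TimeFrequencyMap
from .synthetic import SyntheticLeadfield

__all__ = [
    "write_recording",
    "read_recording",
    "write_leadfield",
    "read_leadfield",
    "write_weights",
    "read_weights",
    "write_tf_map",
]


def write_recording(
    path,
    recording: MultichannelRecording,
    annotations: Optional[Sequence[GroundTruthAnnotation]] = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("fs", data=recording.fs)
        f.create_dataset(
            "labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype()),
        )
        if recording.channel_lobe is not None:
            f.create_dataset(
                "lobes",
                data=np.array(recording.channel_lobe, dtype=h5py.string_dtype()),
            )
        if annotations:
            grp = f.create_group("annotations")
            grp.create_dataset(
                "kind",
                data=np.array([a.kind for a in annotations], dtype=h5py.string_dtype()),
            )
            grp.create_dataset("channel", data=[a.channel for a in annotations])
            grp.create_dataset("onset_s", data=[a.onset_s for a in annotations])
            grp.create_dataset("duration_s", data=[a.duration_s for a in annotations])
            grp.create_dataset(
                "freq_hz",
                data=[
                    np.nan if a.center_frequency_hz is None else a.center_frequency_hz
                    for a in annotations
                ],
            )
            grp.create_dataset("amplitude", data=[a.amplitude for a in annotations])


def read_recording(
    path,
) -> tuple[MultichannelRecording, list[GroundTruthAnnotation]]:
    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
        lobes = None
        if "lobes" in f:
            lobes = [s.decode() if isinstance(s, bytes) else s for s in f["lobes"][()]]
        rec = MultichannelRecording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            channel_labels=labels,
            channel_lobe=lobes,
        )
        annotations: list[GroundTruthAnnotation] = []
        if "annotations" in f:
            grp = f["annotations"]
            kinds = [
                s.decode() if isinstance(s, bytes) else s for s in grp["kind"][()]
            ]
            for i, kind in enumerate(kinds):
                freq = float(grp["freq_hz"][i])
                annotations.append(
                    GroundTruthAnnotation(
                        kind=kind,
                        channel=int(grp["channel"][i]),
                        onset_s=float(grp["onset_s"][i]),
                        duration_s=float(grp["duration_s"][i]),
                        amplitude=float(grp["amplitude"][i]),
                        center_frequency_hz=None if np.isnan(freq) else freq,
                    )
                )
    return rec, annotations


def write_leadfield(path, leadfield: SyntheticLeadfield) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f.create_dataset("positions", data=leadfield.source_positions)
        f.create_dataset("seed", data=leadfield.seed)


def read_leadfield(path) -> SyntheticLeadfield:
    with h5py.File(path, "r") as f:
        return SyntheticLeadfield(
            gain=f["gain"][()],
            source_positions=f["positions"][()],
            seed=int(f["seed"][()]),
        )


def write_weights(path, weights: BeamformerWeights) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=weights.weights)
        f.create_dataset("orientations", data=weights.orientations)
        f.attrs["normalization"] = weights.normalization


def read_weights(path) -> BeamformerWeights:
    with h5py.File(path, "r") as f:
        return BeamformerWeights(
            weights=f["weights"][()],
            orientations=f["orientations"][()],
            normalization=str(f.attrs.get("normalization", "unit-noise-gain")),
        )


def write_tf_map(path, tf_map: TimeFrequencyMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("S_real", data=tf_map.values.real)
        f.create_dataset("S_imag", data=tf_map.values.imag)
        f.create_dataset("freqs", data=tf_map.freqs_hz)
        f.create_dataset("fs", data=tf_map.fs)
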