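"""Shared fixtures.

The expensive end-to-end simulation (8 channels x 60 s with injected ripples
and spike confounders, full detection on every channel) is built once per
session and shared between the detector tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import megripple as mr
from megripple.detector import DetectorConfig, detect_recording

E2E_SEED = 20260918
FS = 1250.0


@pytest.fixture(scope="session")
def detector_config() -> DetectorConfig:
    """Default config with the band-pass designed once for the session."""
    cfg = DetectorConfig()
    cfg.bandpass(FS)
    return cfg


@pytest.fixture(scope="session")
def e2e_world(detector_config):
    """60 s, 8-channel synthetic world and its full detection results.

    Channels 0-3 carry 10 injected ripples (5x ripple-band RMS) and 6 spike
    transients between them; channels 4-7 are pure 1/f background.
    """
    rec, anns = mr.simulate_recording(
        n_channels=8,
        duration_s=60.0,
        fs=FS,
        n_ripples=10,
        n_spikes=6,
        seed=E2E_SEED,
        channels=[0, 1, 2, 3],
    )
    results = detect_recording(rec, detector_config, seed=E2E_SEED + 1)
    return {"recording": rec, "annotations": anns, "results": results}


def overlapping_events(results, annotation, fs=FS):
    """Accepted events overlapping one ground-truth annotation."""
    t0 = annotation.onset_s
    t1 = annotation.onset_s + annotation.duration_s
    res = results[annotation.channel]
    return [ev for ev in res.events if ev.start_s < t1 and t0 < ev.end_s]


def overlaps_any(ev, annotations, kind=None):
    for a in annotations:
        if kind is not None and a.kind != kind:
            continue
        if a.channel == ev.channel and ev.start_s < a.onset_s + a.duration_s \
                and a.onset_s < ev.end_s:
            return True
    return False
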