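"""Per-patient summaries, lobar concordance labels, and cohort statistics.

The cohort table mirrors the published per-patient results: number of virtual
sensors, recording duration, ripple-times (moments with a ripple in at least
one channel), number of virtual sensors with ripples, ripple-times per minute,
and lobar concordance labels against MEG spike dipoles and the resection.
Concordance is classified good "+", moderate "=", bad "-" at the lobar level:
for spikes, good when *all* ripple lobes are spike lobes and moderate when
*any* is; for the resection, good when more than half of the ripple locations
fall inside resected lobes, bad when none do.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recording import LOBE_VOCABULARY
from .triage import RippleTime

__all__ = [
    "GOOD",
    "MODERATE",
    "BAD",
    "NONE",
    "PatientSummary",
    "load_table2_fixture",
    "load_lobe_map",
    "summarize_patient",
    "classify_spike_concordance",
    "classify_resection_concordance",
    "cohort_statistics",
    "paired_rate_test",
]

GOOD, MODERATE, BAD, NONE = "+", "=", "-", "none"

_TABLE2_SHA256 = "2758fb7463c455f1758d3d30183c8b1021df77209ef7024df52795727a8adf81"
_LOBEMAP_SHA256 = "d06a96f3ec6692867aac700caeccef0ca8c89cc014d5174fc59a146a4c4f715d"

#: Expected column schema of the cohort table.
COHORT_COLUMNS = [
    "patient",
    "n_virtual_sensors",
    "duration_min",
    "ripple_location",
    "spike_concordance",
    "resection_concordance",
    "ripple_times",
    "channels_with_ripples",
    "rate_per_min",
    "spike_resection_concordance",
]


@dataclass
class PatientSummary:
    """Per-patient detection summary in cohort-table units."""

    patient: object
    n_virtual_sensors: int
    duration_min: float
    n_ripple_times: int
    n_channels_with_ripples: int
    rate_per_min: float
    ripple_lobes: list[str]
    spike_concordance: str = NONE
    resection_concordance: str = NONE

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels_with_ripples > self.n_virtual_sensors:
            raise ValueError("more channels with ripples than virtual sensors")
        expected = self.n_ripple_times / self.duration_min
        if abs(self.rate_per_min - expected) > 0.005 + 1e-9:
            raise ValueError("rate_per_min inconsistent with counts (beyond rounding)")


def _read_packaged(name: str, sha256: str) -> bytes:
    data = resources.files("megripple.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != sha256:
        raise ValueError(f"packaged fixture {name} is corrupted (checksum mismatch)")
    return data


def load_lobe_map() -> dict[str, list[str]]:
    """Mapping from the cohort table's location strings to canonical lobes."""
    raw = json.loads(_read_packaged("lobe_map.json", _LOBEMAP_SHA256))
    raw.pop("_comment", None)
    return raw


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 25-patient cohort table (checksum-verified).

    Adds a ``ripple_lobes`` column derived from the packaged location-string
    mapping. ``rate_per_min`` is NaN for patients without ripples, matching
    the published table.
    """
    import io

    data = _read_packaged("table2.csv", _TABLE2_SHA256)
    df = pd.read_csv(io.BytesIO(data))
    if list(df.columns) != COHORT_COLUMNS:
        raise ValueError("cohort fixture has unexpected columns")
    if len(df) != 25:
        raise ValueError(f"cohort fixture must have 25 rows, found {len(df)}")
    lobe_map = load_lobe_map()
    df["ripple_lobes"] = df["ripple_location"].map(
        lambda s: list(lobe_map.get(s, []))
    )
    return df


def summarize_patient(
    accepted_events: Sequence,
    ripple_times: Sequence[RippleTime],
    duration_min: float,
    n_virtual_sensors: int,
    patient: object = None,
    channel_lobes: Optional[Mapping[int, str]] = None,
) -> PatientSummary:
    """Summarize one patient's reviewed detections.

    Counts accepted ripple-times, distinct channels carrying at least one
    accepted event, and the ripple-time rate per minute (2-decimal rounding,
    as printed in the cohort table).
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    n_rt = sum(1 for rt in ripple_times if rt.decision != "rejected")
    channels = {ev.channel for ev in accepted_events}
    rate = round(n_rt / duration_min, 2)
    lobes: list[str] = []
    if channel_lobes is not None:
        lobes = sorted({channel_lobes.get(ch, "unknown") for ch in channels})
    return PatientSummary(
        patient=patient,
        n_virtual_sensors=n_virtual_sensors,
        duration_min=duration_min,
        n_ripple_times=n_rt,
        n_channels_with_ripples=len(channels),
        rate_per_min=rate,
        ripple_lobes=lobes,
    )


def _check_lobes(lobes: Iterable[str], what: str) -> list[str]:
    lobes = list(lobes)
    bad = set(lobes) - LOBE_VOCABULARY
    if bad:
        raise ValueError(f"unknown {what} lobe tokens: {sorted(bad)}")
    return lobes


def classify_spike_concordance(
    ripple_lobes: Iterable[str], spike_lobes: Iterable[str]
) -> str:
    """Good "+" if all ripple lobes are spike lobes, moderate "=" if any is,
    bad "-" for disjoint sets, "none" without ripples or spikes."""
    ripple = _check_lobes(ripple_lobes, "ripple")
    spikes = set(_check_lobes(spike_lobes, "spike"))
    if not ripple or not spikes:
        return NONE
    inside = [l in spikes for l in ripple]
    if all(inside):
        return GOOD
    if any(inside):
        return MODERATE
    return BAD


def classify_resection_concordance(
    ripple_lobe_counts: Mapping[str, int],
    resection_lobes: Optional[Iterable[str]],
    half_label: str = MODERATE,
) -> str:
    """Good "+" if > 50% of ripple locations fall in resected lobes, bad "-"
    if none do, moderate "=" otherwise.

    ``ripple_lobe_counts`` maps lobe -> number of ripple locations (virtual
    sensors with ripples) in that lobe. The published rule leaves exactly 50%
    undefined; it is labelled moderate by default (``half_label``). Without
    resection information the label is "none".
    """
    if resection_lobes is None:
        return NONE
    resection = set(_check_lobes(resection_lobes, "resection"))
    if not resection:
        return NONE
    _check_lobes(ripple_lobe_counts.keys(), "ripple")
    if any(c < 0 for c in ripple_lobe_counts.values()):
        raise ValueError("lobe counts must be non-negative")
    total = sum(ripple_lobe_counts.values())
    if total == 0:
        return NONE
    inside = sum(c for l, c in ripple_lobe_counts.items() if l in resection)
    frac = inside / total
    if frac > 0.5:
        return GOOD
    if frac == 0.0:
        return BAD
    if frac == 0.5:
        return half_label
    return MODERATE


def cohort_statistics(table: pd.DataFrame) -> dict:
    """Cohort-level statistics over a table with the fixture schema.

    Means of ripple-times, channels-with-ripples and rate are taken over the
    patients *with* ripples; the Spearman rank correlation (average-rank tie
    handling) of total virtual sensors vs channels-with-ripples uses all
    patients.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    with_ripples = table[table["ripple_times"] > 0]
    n_with = len(with_ripples)
    rho, p = stats.spearmanr(
        table["n_virtual_sensors"], table["channels_with_ripples"]
    )
    rates = with_ripples["rate_per_min"].astype(float)
    spike_counts = (
        with_ripples["spike_concordance"].fillna(NONE).value_counts().to_dict()
    )
    resection_counts = (
        with_ripples["resection_concordance"].fillna(NONE).value_counts().to_dict()
    )
    return {
        "n_patients": int(len(table)),
        "n_patients_with_ripples": int(n_with),
        "mean_ripple_times": float(with_ripples["ripple_times"].mean()),
        "mean_channels_with_ripples": float(
            with_ripples["channels_with_ripples"].mean()
        ),
        "mean_rate_per_min": float(rates.mean()),
        "spearman_rho_vs_channels": float(rho),
        "spearman_p": float(p),
        "spike_concordance_counts": spike_counts,
        "resection_concordance_counts": resection_counts,
    }


def paired_rate_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Generic Wilcoxon signed-rank comparison of paired per-patient counts
    (e.g. automatic vs visual ripple-times). Untargeted utility."""
    res = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
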