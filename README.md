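# megripple

Automatic detection of **ripples** — high-frequency oscillations (HFOs) in the
80–250 Hz band — in magnetoencephalography (MEG), for epilepsy biomarker
analysis. Ripples in invasive EEG mark epileptogenic tissue; finding them
non-invasively in MEG is hard because they are tiny against the background
noise and because a whole-head analysis involves thousands of channels, far
too many to review by eye. This package implements a clinical pipeline that
makes that tractable:

1. **Beamformer virtual sensors** — a scalar (SAM-type) minimum-variance
   beamformer reconstructs source-space time series from sensor data and
   supplied leadfields, raising the signal-to-noise ratio of local
   oscillations.
2. **Automatic ripple detection** per channel, adapted from the
   Stockwell-entropy detector family.
3. **Triage for review** — co-occurring detections are grouped into
   *ripple-times*, at most three events per ripple-time are sampled for visual
   review, and the reviewers' verdicts decide whole groups.
4. **Cohort summaries** — per-patient rates, lobar concordance labels against
   spike dipoles and resections, and cohort statistics.

Everything is exercised on synthetic signals with exact ground truth (1/f
background plus injected ripples, spike transients and EMG bursts) and on a
packaged 25-patient cohort table.

## The detector

Each channel `x(t)` (sampled at 1250 Hz) is band-pass filtered with an
elliptic filter whose single-pass response has −3 dB points at 70 and 253 Hz,
≥ 60 dB stopband attenuation and ≤ 0.5 dB passband ripple. Detection is
two-step:

**Baseline.** The Stockwell (S-)transform

    S(τ, f) = ∫ x(t) · (|f|/√(2π)) · exp(−(τ−t)² f² / 2) · e^(−i2πft) dt

is computed for 120 random 1 s epochs, and the per-sample Stockwell entropy
`H(τ) = −Σ_f p(τ,f) ln p(τ,f)` with `p(τ,f) = |S|²/Σ_f |S|²` classifies
samples with `H > 0.85 · H_max` as baseline (noise-like spectrum).

**Events.** The Hilbert envelope of the band-passed signal over all baseline
samples forms a CDF; its 98th percentile is the channel threshold. Envelope
excursions above threshold lasting ≥ 20 ms are candidates, and a candidate is
a ripple only if

- *(a) entropy stability*: over the event interior,
  `max H < 1.25 · min H`;
- *(b) amplitude*: the peak |x| inside the event exceeds the flank amplitude
  plus one SD of |x| over 1000 samples on each side;
- *(c) spectral distinctness*: the event's power spectral density shows a
  distinct local peak in (40, 250] Hz preceded by a trough at a lower
  frequency.

All criteria are relative, so the detector is invariant to rescaling of the
channel. See `docs/methods.md` for the numerical choices and their rationale.

## Worked example

```python
import megripple as mr
from megripple.detector import DetectorConfig, detect_recording, events_to_frame
from megripple.triage import group_ripple_times, build_review_set, apply_review_decisions

# 4 channels x 60 s of 1/f background; 6 ripples + 3 spike confounders
# injected on channels 0-1 (amplitudes relative to local background RMS)
rec, truth = mr.simulate_recording(
    n_channels=4, duration_s=60.0, n_ripples=6, n_spikes=3,
    seed=7, channels=[0, 1],
)
results = detect_recording(rec, DetectorConfig(), seed=7)
events = [ev for res in results for ev in res.events]
print(f"{sum(len(r.candidates) for r in results)} candidates, "
      f"{len(events)} accepted ripples on "
      f"{len({ev.channel for ev in events})} channels")

times = build_review_set(group_ripple_times(events), rng=7)
decisions = {i: True for rt in times for i in rt.review_ids}   # reviewer says yes
accepted, rejected = apply_review_decisions(times, decisions, events)
print(f"{len(times)} ripple-times -> rate "
      f"{len(times) / (rec.duration_s / 60):.2f} per minute")
```

prints

```
17 candidates, 6 accepted ripples on 2 channels
6 ripple-times -> rate 6.00 per minute
```

i.e. the detector recovered all six injected ripples, rejected the spike
transients and the chance envelope excursions (11 of 17 candidates failed at
least one validation), and the triage stage grouped the survivors into six
reviewable ripple-times. `events_to_frame(results)` exposes per-event features
(peak envelope, entropy range, PSD trough/peak frequencies) and the three
validation flags for auditing.

The same steps are available from the shell:

```bash
megripple simulate --channels 4 --duration 60 --ripples 6 --seed 7 --out rec.h5
megripple detect --rec rec.h5 --seed 7 --out events.csv
megripple triage --events events.csv --seed 7 --out review.csv
megripple summarize --out cohort_summary.json   # packaged 25-patient table
```

## Acceptance script

`scripts/acceptance.py` re-designs the ripple band-pass at 1250 Hz from
scratch, measures its realized single-pass magnitude response on a dense
frequency grid, and reports the located −3 dB crossings, the minimum stopband
attenuation and the maximum passband deviation as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/megripple/synthetic.py` — seeded 1/f background, event injection,
  synthetic leadfields
- `src/megripple/filters.py` — elliptic band-pass (−3 dB edge calibration),
  high-pass, band-stop, zero-phase application
- `src/megripple/stockwell.py` — S-transform (FFT-based + direct-definition
  reference) and Stockwell entropy
- `src/megripple/beamformer.py` — covariance estimation, scalar weights,
  virtual-sensor reconstruction
- `src/megripple/detector.py` — baseline, threshold, candidates, the three
  validation criteria
- `src/megripple/triage.py` — ripple-times, review sampling, decision
  propagation
- `src/megripple/cohort.py` — per-patient summaries, concordance labels,
  cohort statistics, packaged cohort table
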