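# Methods

This note records the models and numerical choices behind `megripple`: what
each stage computes, which parameters matter, what the synthetic world does
and does not emulate, and where the design was genuinely open.

## Signal model and synthetic world

The generator emulates the statistical skeleton of a resting-state MEG
virtual-sensor recording, not its physiology:

- **Background**: Gaussian noise spectrally shaped to `1/f^alpha` (default
  `alpha = 1`) by FFT-domain filtering, each channel rescaled to an exact
  target RMS. Channels are independent — there is no sensor cross-talk, no
  head movement, no mains or cardiac interference.
- **Ripple**: a sinusoid (default 100–140 Hz) times a Tukey window (taper
  fraction 0.25), 40–80 ms long. Amplitude is specified as a multiple of the
  local ripple-band (80–250 Hz) RMS of the background over the event span, so
  tests are scale-free; the default of 5x is a plausibly review-worthy event,
  not a calibration against patient data (no amplitude distribution for real
  MEG ripples is available).
- **Spike**: a difference-of-Gaussians biphasic transient (20–70 ms) whose
  widths put the dominant energy below 30 Hz, plus a small exponential cusp at
  the apex. The cusp contributes the broadband `1/f²` spectral edge of a
  sharp transient: filtering it rings the ripple band without creating any
  spectral peak above 40 Hz. This is the classic detector confounder.
- **EMG burst**: 60–300 Hz band-passed noise, ≥ 200 ms, Tukey-windowed.

All generators are pure functions of their arguments including the seed, and
injection is strictly additive and confined to the annotated span. A green
end-to-end test therefore establishes that the detector behaves correctly in
this stated world; it does not establish clinical sensitivity or specificity
on real MEG, whose artifact zoo and spatial correlations are absent here.

## Filters

The front-end band-pass is elliptic. Its contract is stated on the single-pass
magnitude response: −3 dB crossings at 70 and 253 Hz, ≥ 60 dB attenuation
beyond the stopband edges (defaults 55 and 290 Hz; transition widths are not
part of the contract and were chosen as reasonable), ≤ 0.5 dB ripple inside
75–245 Hz. Elliptic designs place their passband edges at the ripple level,
not at −3 dB, so the design edges are calibrated by per-edge bisection (fixed
order from `ellipord`, ≤ 50 iterations, ±0.05 Hz design tolerance) until the
realized −3 dB crossings land on 70/253 Hz. The realized design at 1250 Hz is
order 14 (7 biquads) with crossings at 70.01/253.00 Hz, exactly 60.0 dB
minimum stopband attenuation and exactly 0.5 dB maximum passband deviation
(the equiripple extrema), verified by `scripts/acceptance.py`.

Filtering is applied forward-backward (`sosfiltfilt`), so events keep their
timing across the unfiltered/high-passed/band-passed traces a reviewer sees;
the contract above is defined and tested on the *single-pass* response. The
80 Hz high-pass for the data covariance is a Butterworth of order 8 (≥ 48 dB
one octave below the cutoff, < 0.3 dB above 1.2x the cutoff). A generic
Butterworth band-stop covers head-localization coil tones; no default
frequencies exist because they are acquisition-site specific.

## Stockwell transform and entropy

The discrete S-transform is computed in the frequency domain,
`S[n] = IFFT(X[(m+n) mod N] · exp(−2π²m²/n²))` per voice `n`, with one voice
per DFT frequency of the analysis epoch (1 s at 1250 Hz → 1 Hz bins). An
O(N²) direct-summation implementation of the same definition serves as the
reference oracle in the tests (agreement < 1e-9 relative for N ≤ 128).

Stockwell entropy is the Shannon entropy (natural log) of the per-sample
power distribution over frequency bins; it is invariant to global amplitude
scaling, bounded by `H_max = ln(n_bins)`, and an all-zero column is assigned
`H_max` (maximally uninformative). "Maximum entropy" in the baseline
threshold means the theoretical `ln(n_bins)` by default; an empirical mode
(max over sampled epochs) is available.

## Detector

`DetectorConfig` holds every constant: 120 baseline epochs of 1 s, entropy
threshold 0.85·H_max (strict >), envelope CDF percentile 98 (nearest-rank),
minimum duration 20 ms (25 samples at 1250 Hz, boundary inclusive), merge gap
10 ms (runs separated by strictly less are merged *before* the duration
test), stability ratio 1.25 (strict <), flanks of 1000 samples with 1 SD,
PSD band 40–250 Hz. Sample intervals are 0-based and half-open throughout.

Choices the published description leaves open, and what was done:

- **Which signal carries the baseline entropy.** Computing entropy of the
  band-passed signal over a 40–500 Hz band is degenerate: band-limited white
  noise then sits exactly at the 0.85 threshold (`ln(183)/ln(461) ≈ 0.85`).
  Baseline entropy is therefore computed on the broadband (unfiltered) trace
  over 40–500 Hz, where noise-like samples sit well above the threshold and
  oscillatory events well below. Overlapping epochs vote by union.
- **Entropy stability (criterion a).** The per-sample entropy for this
  criterion is computed on the *band-passed* trace over 80–250 Hz with a
  0.5 s context pad (trimmed afterwards). With a short (±100 ms) pad the
  coarse frequency bins make the entropy of even a clean steady ripple swing
  by ~1.3x over the event, and the 125 % bound rejects nearly everything;
  with fine bins the entropy of a steady narrow-band burst is flat (≤ 1.20
  measured) while events of unstable frequency content remain above. Signal,
  band and pad are configurable (`stability_signal`, `stability_band`,
  `stability_pad_s`).
- **Amplitude criterion (b).** "Flank amplitude + 1 SD" reads the amplitude
  of a flank as its *peak* |x| (the usual clinical meaning for a stretch of
  signal), each flank separately, on the filtered trace; flanks are truncated
  at record edges and need ≥ 250 usable samples. This is what bounds false
  positives: a chance supra-threshold noise excursion rarely clears the peaks
  of its own flanks, while genuine ripples do easily. A mean-based reading
  (`amplitude_mode="mean-flank"`) and a pooled-flanks mode are provided.
- **PSD criterion (c).** The event PSD is the S-transform power averaged over
  the event samples (segment padded ±100 ms, mean removed), which is smooth
  in frequency; a raw periodogram of these ~0.25 s segments scatters by
  ~5.6 dB per bin and finds "peaks" everywhere. The criterion demands a local
  peak in (40, 250] Hz with ≥ 8 dB prominence and a local trough at a lower
  frequency. The 8 dB default is the measured ceiling of chance bumps of 1/f
  background on this estimator; genuine ripples at review-worthy SNR stand
  ≥ 16 dB above their trough. Estimator and prominence are configurable.
- Baseline epochs may by chance overlap events; no exclusion is applied — the
  entropy threshold itself suppresses event samples from the baseline.

With the defaults, the seeded end-to-end simulation (60 s, 8 channels,
ripples at 5x band RMS) recovers ≥ 80 % of injected ripples with onset error
≤ 10 ms, accepts ≤ 1 event per noise-only channel, and rejects ≥ 80 % of
spike confounders by the PSD criterion — these are exactly the quantities the
acceptance tests compute.

## Beamformer

Scalar minimum-variance beamforming with supplied leadfields. For each source
with gain columns `L` (channels × 3): the orientation maximizes the output
power-to-noise ratio, solved as the largest eigenvector of the 3×3
generalized eigenproblem `(LᵀC⁻¹L)θ = λ(LᵀC⁻¹NC⁻¹L)θ` — deterministic, with
the sign fixed by convention. Weights follow the unit-gain closed form
`w = C⁻¹l/(lᵀC⁻¹l)` and are then noise-normalized by `√(wᵀNw)` (unit noise
gain), so noise-covariance-distributed input yields unit output variance.
`C` is the sample covariance of the 80 Hz high-passed recording; `N` comes
from the first 10 s of the unfiltered recording. `C` is diagonally loaded by
`λ·mean(diag C)` with default `λ = 0.05` (no loading is stated in the source
workflow; 5 % is a common choice that keeps the inversion stable when the
covariance window is short). Array-gain normalization was considered and not
implemented; unit-noise-gain is the variant that makes the noise-projection
variance test meaningful. Grey-matter grid construction and forward modelling
are out of scope — source positions and leadfields are inputs.

## Triage and cohort bookkeeping

Ripple-times are connected components of events under temporal interval
overlap across channels (strict overlap by default; a configurable gap can
bridge near-coincident events). Review samples are uniform without
replacement, capped at three per ripple-time; a ripple-time is accepted iff
strictly more than half of its reviewed events are judged true (with a cap of
three this is the "> 2/3" rule), and the decision propagates to all members,
sampled or not.

Concordance at the lobar level uses the fixed vocabulary
{L,R} × {frontal, temporal, parietal, occipital, central} plus "unknown":
spike concordance is good when *all* ripple lobes are spike lobes, moderate
when *any* is, bad otherwise; resection concordance is good when > 50 % of
ripple locations (virtual sensors with ripples) lie in resected lobes, bad
when none do, moderate otherwise — exactly 50 % is labelled moderate
(configurable), since the published >50 %/<50 % rule leaves it undefined.
The packaged 25-patient cohort table ships with a checksum and an explicit
mapping file from its free-text location strings to the lobe vocabulary;
"some widespread" maps to "unknown". Cohort statistics take means over
patients with ripples and the Spearman correlation (average-rank ties, via
scipy) over all patients; a brute-force rank-then-Pearson oracle checks the
correlation in the tests.

## Known limitations

- The synthetic world has independent channels; the beamformer tests inject a
  single coherent source, which is the simplest non-trivial case.
- EDF import/export is not provided (no EDF library in the supported
  environment); the HDF5 container and CSV/JSON exports are the interchange
  formats.
- Detection on raw physical sensors runs mechanically but is uncalibrated;
  the detector's defaults target beamformer virtual sensors.
- Fast ripples (> 250 Hz) are out of scope; the band-pass upper edge and the
  PSD band would both need changing, and the 1250 Hz sampling rate leaves
  little headroom.
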