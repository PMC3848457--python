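# Methods

## The discounted AR model and its recursion

The detector models a single band-passed EEG channel as a zero-mean
AR(p) process whose parameters drift in time. The discounted estimate at
time t minimises the exponentially down-weighted squared prediction
error with forgetting factor (1−r) per sample. The sequential recursion
maintains, per sample: the gain matrix `V_t`, the weighted
cross-moment vector `M_t`, the coefficients `A_t = V_t M_t`, the model
mean `mu_t = A_t' xbar_t`, the exponentially weighted variance
`sigma2_t = (1−r) sigma2_{t−1} + r (x_t − mu_t)^2`, and the quadratic
loss `psi_t = (x_t − mu_t)^2`. Inverting the `V` recursion shows
`V_t^{-1} = r · Σ (1−r)^{t−i} xbar_i xbar_i' + (1−r)^{t−p} I`, i.e. the
recursion solves the discounted least-squares problem with a ridge term
that decays geometrically from the identity initialisation; the test
suite verifies agreement with batch weighted normal equations once that
ridge has decayed (max coefficient difference ~2e−3 from ~60 samples
after initialisation at r = 0.1; at the 10p-th sample the ridge is still
O(1) and the two estimators legitimately differ).

The published step order is kept exactly: the coefficients are updated
with the incoming observation *before* the mean and loss are computed,
so `psi_t` is a partially in-sample residual. This is a deliberate
faithfulness choice over one-step-ahead purity — swapping the order
changes the loss trace only marginally at r ≤ 0.01 but would no longer
be the stated algorithm.

**Initialisation.** `M` and `sigma2` start from a Burg AR fit (via
statsmodels) of a training segment, default the first 10 s of data; the
training-segment mean is subtracted from the whole series once (the
model assumes zero mean; band-passed EEG is already near zero-mean).
`V` starts at the identity and `c` at `r·xbar'xbar`.

**Numerical guards.** `V` is symmetrised as `(V + V')/2` each step
(asymmetry stays < 1e−9 relative over 1e5 random steps in the tests);
`sigma2` is floored at 1e−12 so constant segments cannot produce a
zero-variance degeneracy; a non-positive `1 − r + c` raises instead of
propagating a broken gain. `psi_t` for t ≤ p is defined as 0 and
excluded from smoothing/thresholding.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| order p | 1 | AR order; 1–2 suffices for narrowband-filtered EEG |
| discount r | 0.01 | forgetting rate per sample; 0.01–0.001 at 128 Hz. Scale inversely with sampling rate. |
| train_s | 10 s | Burg initialisation span |
| smooth window | 5 samples | moving-mean width of the loss; sets the effective temporal resolution (~40 ms at 128 Hz) |
| vote fraction | 1/3 | a sample counts when ≥ ceil(fraction × n_channels) channels flag it |
| merge / prune | 250 ms / 250 ms | gaps shorter than merge are fused, then isolated events shorter than prune are dropped (merge first, so short fragments near a large event survive) |
| beta | 2 | F-measure weight; favours recall, appropriate for rare events (<1% of time) |
| fuzzy window | 0.1 s | boundary tolerance in evaluation |

A larger r (> 0.05) adapts so fast that the model learns the burst
itself and the loss statistic loses contrast.

## Evaluation semantics

The comparison rasterises both interval sets on the sample grid at `fs`,
so the four state durations partition the compared span exactly (to one
sample). The fuzzy window is a boundary tolerance: FP/FN samples within
`fuzzy_s` of an Agreement region (the region dilated by `fuzzy_s` on
each side) are reassigned to Agreement. This realisation keeps the
comparison symmetric under swapping the two labelings (with FP and FN
exchanged) and makes agreement monotone in the window width; it is an
operational reconstruction of the published description, not a
bit-for-bit port of any toolbox. Hit rate counts truth events touched by
at least one detected sample; the temporal error statistic is total FN
time divided by the number of truth events. Threshold selection sweeps
200 quantile-spaced candidates over the pooled smoothed-loss
distribution (ties resolve to the smallest threshold); ROC points use
the time-based recall and one-minus-specificity of the same pipeline.
The train/test protocol splits the recording into two continuous equal
halves at the midpoint sample and applies the first half's threshold
unchanged to the second.

Settling time after a coefficient change is reported as the first sample
at which all coefficient estimates enter a ±0.15 band around the
post-change truth. A stricter "enter and never leave" variant is
implemented too, but at r = 0.01 the steady-state estimator noise leaves
a ±0.15 band a few percent of the time indefinitely, so that variant
measures the last noise excursion rather than the tracking response.

## The spectral baseline

The comparison detector computes the amplitude spectral density of 1 s
Hamming-windowed segments (250 ms slide), finds the largest peak in
[3, 40] Hz, and, when the peak lies in [8, 13] Hz, measures its full
width at half maximum by linear interpolation of the half-maximum
crossings; a segment is a spindle when FWHM < 2 × 1.37 Hz (twice the
Hamming noise bandwidth at 1 Hz resolution). A one-parameter exponential
`exp(γf)` fitted by least squares to the spectrum outside the peak's
FWHM band estimates the 1/f-like background; the oscillation index is
the ratio of spectral to background area over the FWHM band, computed on
a dense interpolated grid because the band often spans few native 1 Hz
bins. The index is reported, not thresholded. The `exp(γf)` form is one
reading of an ambiguous printed formula (`exp(f^γ)` being the other);
the log-linear decay is the standard choice on this scale and the
alternative would change only the reported index, not the FWHM gate.
Classification is invariant to rescaling the input window. Note the
one-parameter form has no amplitude degree of freedom, so γ absorbs
both shape and scale; on white noise the criterion fires on chance
narrow alpha peaks in roughly 5–25% of windows, consistent with the low
precision this family of detectors shows on unfiltered data.

## Synthetic data

Two generator families, both bit-reproducible given (spec, seed):

* **Piecewise AR processes.** Segments of (coefficients, innovation sd,
  length) with lag carry-over across boundaries and a 500-sample burn-in
  before the first segment so it starts in its stationary regime.
  Non-stationary segments are rejected. The two stock configurations are
  an AR(2) coefficient change (0.6, −0.2) → (0.4, −0.6) at sample 2000
  (n = 4000, unit innovations) and the same AR(2) with an innovation-sd
  change 1 → 2 at sample 2000.
* **Burst-over-noise EEG.** 33 channels on a 10–10 mosaic at 300 Hz,
  white Gaussian background at 3 µV RMS per channel, and twenty 500 ms
  bursts of a 10 Hz sinusoid every 5 s starting at 10 s, with a 10%
  cosine (Tukey) taper to avoid spectral splatter from rectangular
  onsets. Bursts project onto the montage through fixed spatial gains —
  Gaussian fall-off from two symmetric parietal-occipital centres,
  normalised to 1 at the best-coupled channel — rather than a dipole
  forward model; the SNR sweep, which is what the validation rests on,
  is preserved. SNR is defined as burst peak amplitude on the
  best-coupled channel divided by the background RMS (an SNR of 2 means
  a 6 µV peak over 3 µV RMS noise).

What the generator does **not** emulate: 1/f background spectra,
spontaneous (unlabelled) alpha, eye/muscle artifacts, inter-channel
noise correlation from volume conduction, or spindle amplitude/duration
variability. Detection scores on these fixtures are therefore upper
bounds: with a white background, the [6, 15] Hz band-pass removes most
noise power and the in-band SNR is far higher than the nominal broadband
SNR, which is why the simulated F₂ stays above 0.97 across the whole
nominal SNR sweep while real recordings with spontaneous alpha and
artifacts produce substantially lower precision. The pipeline-level
claims the fixtures do support: correct change-point tracking, correct
evaluation algebra, monotone improvement with SNR, and end-to-end
recovery of every scheduled burst at SNR ≥ 1.

**Preprocessing.** Polyphase anti-aliased resampling (300 → 128 Hz),
then a Butterworth band-pass of total order 8 at [6, 15] Hz applied
forward-backward (zero phase; the effective attenuation doubles — a
3 Hz tone is attenuated > 75 dB). Offline analysis is zero-phase by
default because labelled boundaries align with the band-passed signal;
a causal option exists for online use, where detection additionally
incurs the ≥ 250 ms confirmation delay of the prune rule.

## Problem sizes

The stock studies are deliberately desk-scale: 4000-sample AR runs (20
seeded replicates), a 110.5 s, 33-channel EEG simulation per SNR, and
200-point threshold sweeps. The full test suite runs in ~25 s and the
acceptance script in ~15 s on one CPU.

## Known limitations

* The loss statistic is a partially in-sample residual by construction
  (published step order); its absolute scale depends on r.
* Thresholds are global per recording; no per-channel or adaptive
  re-estimation.
* The evaluation's fuzzy reassignment is symmetric (both FP and FN near
  agreement become agreement); toolboxes that reassign FP mass to Null
  instead will report slightly different specificity at nonzero fuzzy
  windows.
* EDF files are read (via mne) but written as CSV + YAML sidecar; no
  EDF export.
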