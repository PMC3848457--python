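# spindar

Online detection of short narrowband oscillatory bursts in EEG —
*alpha spindles* — using sequential discounted autoregressive (SDAR)
change-point models.

Alpha spindles are 0.5–2 s bursts of high-amplitude alpha ([8, 13] Hz)
activity, prominent over parietal/occipital cortex and associated with
fatigue and drowsiness. A spindle is a sudden change in the statistical
structure of the band-passed EEG, so it can be found by change-point
methods: fit a time-varying autoregressive model whose memory of the past
decays geometrically, and flag the moments when the model's one-step
prediction fails.

`spindar` is for EEG researchers and BCI engineers who need a fast,
statistically grounded burst detector with per-sample temporal
resolution, plus the machinery to evaluate it: a four-state labelled
interval comparison with a fuzzy boundary window, weighted-F-measure
threshold tuning, ROC curves, a spectral (FWHM-of-the-alpha-peak)
baseline detector, and seeded synthetic generators with exact ground
truth.

## The model

A zero-mean series $x_t$ follows an AR($p$) model
$x_t = \sum_{i=1}^{p} A_i x_{t-i} + \varepsilon_t$,
$\varepsilon_t \sim N(0, \sigma^2)$. The *discounted* AR model makes the
coefficients time-dependent by down-weighting the past with a discounting
rate $r \in (0,1)$:

$$\hat A_t = \arg\min_A \sum_{i=p+1}^{t} (1-r)^{t-i}\,\bigl(x_i - A^\top \bar x_i\bigr)^2,
\qquad \bar x_i = (x_{i-1}, \dots, x_{i-p})^\top .$$

The SDAR recursion maintains $\hat A_t$ online with rank-one updates of a
gain matrix $V_t$ (initialised from a Burg fit of a training segment),
together with the model mean $\mu_t = \hat A_t^\top \bar x_t$, the
exponentially weighted variance
$\sigma_t^2 = (1-r)\sigma_{t-1}^2 + r (x_t-\mu_t)^2$, and the quadratic
loss $\psi_t = (x_t - \mu_t)^2$. The smoothed loss (5-point moving mean)
is the detection statistic: spindles are maximal runs above a threshold,
combined across channels by a 1/3 vote, merged over gaps < 250 ms and
pruned below 250 ms. The threshold maximises
$F_\beta = (1+\beta^2)\,PR/(\beta^2 P + R)$ with $\beta = 2$ against a
labelled event set, where precision $P$ and recall $R$ are computed from
the *durations* of the four comparison states (Agreement, Null
Agreement, False Positive, False Negative).

## Worked example

Simulate the 20-burst ground-truth study (10 Hz bursts, 500 ms, every
5 s from the 10 s mark, 3 µV RMS background, SNR 3), preprocess
(downsample to 128 Hz, order-8 Butterworth band-pass [6, 15] Hz), detect
on the parietal/occipital channels, and evaluate:

```python
from spindar import (SpindleSimSpec, SpindleDetector, simulate_spindle_eeg,
                     preprocess, compare_labels)

spec = SpindleSimSpec(snr=3.0, seed=0)          # 20 bursts, 10 Hz, 500 ms
data, truth, labels = simulate_spindle_eeg(spec)
proc, fs = preprocess(data, spec.fs_gen, (6, 15), 8, fs_out=128.0)

posterior = [i for i, l in enumerate(labels) if l.startswith(("P", "O"))]
det = SpindleDetector(proc[posterior], fs, [labels[i] for i in posterior],
                      order=1, discount=0.01)
res = det.fit()
tau, curve = res.optimize_threshold(truth, beta=2.0, fuzzy_s=0.0)
print(res.summary())
print(compare_labels(truth, res.events(), 0.0, res.total_dur_s, fs=fs).summary())
```

prints

```
Spindle detection (SDAR loss scoring)
=====================================
Channels:      12 (P7, P3, Pz, P4, P8, PO7, PO3, POz, PO4, PO8, O1, O2)
Sampling rate: 128.0 Hz
Order / r:     1 / 0.01
Vote fraction: 0.333
Merge / prune: 250 ms / 250 ms
Threshold tau: 1.624
Events:        20 (10.23 s total)

Sensitivity/Recall  0.998
Specificity         0.997
Precision           0.975
Hit Rate            100.00% (20/20)
Temporal Error      ~1 ms
Agreement           9.977 s
Null Agreement      100.242 s
False Negative      0.023 s
False Positive      0.258 s
```

All 20 simulated bursts are recovered (hit rate 100%), the time-based
recall/specificity are ≈ 1, and the residual boundary error (false
negative time per event) is about a millisecond at this SNR. The tuned
threshold `tau` is in units of squared microvolts of one-step prediction
error.

The same pipeline is available from the shell:

```sh
spindar simulate --model spindles --snr 3 --seed 0 --out-dir fix/
spindar detect --input fix/spindles_signal.csv --truth fix/spindles_truth.tsv \
               --resample 128 --fuzzy 0 --out-dir out/
spindar compare --truth fix/spindles_truth.tsv --detected out/events.tsv --fuzzy 0.1
```

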