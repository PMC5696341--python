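# Methods

`endoflow` quantifies how cultured endothelial monolayers respond to fluid
flow, from three kinds of raw material: single-channel calcium-indicator
movies, stained cell/junction images, and gridded velocity fields from
phase-contrast velocimetry.  Everything below is the package's own account of
the models it implements, the defaults it ships, and what its synthetic
benchmarks do and do not establish.

## Calcium trace pipeline

### Acquisition model

A recording is a fluorescence trace F(t) (arbitrary units, 1 s sampling)
with three phases: a ~10 min *flow* phase in which calcium spikes occur, a
3 min *ionomycin* phase that saturates the indicator (per-cell maximum
Fmax), and a 3 min *EDTA* phase that chelates calcium (per-cell minimum
Fmin).  Segmentation is deliberately simple: average all frames, threshold
with Otsu's method, label 4-connected components, and average each label's
pixels per frame.  Touching cells are not split; in a confluent monolayer
this under-segments, a documented limitation.

### Photobleach correction

Slow bleaching is modelled as

    trend(t) = c0 + c1 t + c2 t^2 + amp exp(t / tau),   c1 <= 0, tau < 0,

fitted to the flow phase by Levenberg–Marquardt (lmfit) under the asymmetric
loss L = r^2 (sign(r) + alpha)^4, r = prediction − measurement.  With
0 < alpha < 1, overestimates cost ((1+alpha)/(1−alpha))^4 times more than
underestimates, so spikes — wide upward excursions — barely attract the
trend, which instead tracks the baseline beneath them.  Defaults: alpha =
0.8; L2 weight on c2 of 1e−6 × trace range (a stabiliser, not a tuning
knob); initialisation c0 = median(F), c1 = c2 = 0, amp = F(0) − median(F),
tau = −span/3.

Numerical notes.  The loss has a gradient kink at r = 0; MINPACK sometimes
reaches its evaluation cap without formally meeting its tolerance even
though the trend has plateaued at the noise floor — such fits are returned
with `converged=False` and are typically usable.  For alpha ≥ 1 the loss is
exactly zero for all underestimates, so the trend can sink indefinitely
once it passes below the data; the per-trace alpha selector (below)
penalises the resulting baseline bias and avoids this region in practice.
The fitted trend settles two-to-three noise SDs *below* the baseline (it
tracks the lower envelope of the noise); this constant offset is harmless
because downstream thresholds are relative to the corrected trace's median.

Per-trace alpha selection scans {0.2, …, 2.0} and keeps the value minimising
|median(F − trend)| over the sub-median samples (baseline fidelity).  Flat
criteria (within optimiser precision, 1e−4 of range) fall back to 0.8.

Detrending subtracts the trend and re-anchors at trend(last flow sample):
F_corr = F − trend + trend(t_end).  Re-anchoring keeps the corrected flow
phase commensurable with the *uncorrected* Fmin/Fmax phases recorded
immediately afterwards.  Subtraction treats bleaching as additive; if the
true attenuation is multiplicative (the generator's default), spike
amplitudes carry a small residual bias (about the total attenuation across
the recording, a few percent here), quantified by the recovery tests.

### Calibration and spike statistics

Concentration follows the single-wavelength indicator relation
Ca(t) = Kd (F − Fmin)/(Fmax − F) with Kd = 170 nM (OGB-1).  Fmax and Fmin
are per-cell medians of the last 30 samples of their phases (robust to the
switching transient).  Samples outside (Fmin, Fmax) are clamped into
[0, 10 Kd] and flagged rather than propagated as infinities.

Noise is estimated robustly: baseline = median(Ca); noise SD = the median
absolute deviation over the samples at or below the 75th percentile —
computed that way so the spikes being detected cannot inflate their own
threshold — rescaled by 1/Φ⁻¹(0.6875) ≈ 2.046, the factor that makes the
truncated estimator unbiased for Gaussian noise (the classic 1.4826 applies
only to the untruncated MAD).

A spike is a maximal run of samples strictly above baseline + 2 × noise SD
lasting at least 3 s.  Runs are not merged; no sub-threshold gap is
tolerated.  Duration = samples-above-threshold × dt.  Amplitude = highest
concentration in the run relative to baseline.  AUC = trapezoidal area of
(Ca − min Ca over the whole trace) across the run window (a whole-trace
variant is also provided, as the per-trace reading of "total area" is
defensible too).  Group contrasts use the Mann–Whitney U test (exact by
enumeration when both groups have ≤ 8 values and no ties; otherwise a
normal approximation with tie and continuity corrections) and Welch's
t-test.

## Synthetic data

The generator inverts the calibration formula to paint a known Ca(t) into
fluorescence, multiplies by a normalised bleaching trend (additive mode
available), appends ionomycin/EDTA phases that relax exponentially to
Fmax/Fmin (10 s settling constant), and adds Gaussian noise.  Spikes are
boxcars with durations quantised to the sampling grid, so duration and
amplitude ground truth is exact for detector testing.  Bleaching continues
through the calibration phases, as it does under continuous illumination.

Condition presets encode the two flow-onset populations studied: control
("scramble", n = 347, responder probability 0.87, amplitude 4.1 nM,
duration 8.6 s, baseline 125 nM) and NOTCH1 knockdown ("kd", n = 339,
responder probability 0.94, amplitude 7.8 nM, duration 10.7 s, baseline
121 nM).  Per-cell SDs are reconstructed from the published SEMs as
SEM × √n.  Amplitudes and durations are drawn from lognormal distributions
matched to those means and SDs: positive support with the *exact* target
mean, where a normal truncated at zero would inflate the mean by ~50% at
these coefficients of variation.  The knockdown duration SD reconstructed
this way (≈ 75 s at a 10.7 s mean) is extreme — most drawn spikes are
shorter than the 3 s detectability floor and occasional draws span minutes;
spikes are placed longest-first into free gaps of the flow phase, clipped
to the largest remaining gap when a draw cannot fit, and dropped when the
phase is fully occupied (the recorded truth is always exactly what was
painted).

Defaults chosen where the source material is silent, fixed once: trace
noise SD 0.2 a.u. (≈ 0.2 nM at the default calibration — traces average
whole-cell ROIs of hundreds of pixels, and published example traces resolve
4 nM spikes cleanly); per-cell baseline SD 5 nM; Fmin ≈ 100 ± 5, Fmax ≈
600 ± 20 a.u.; bleach trend (c0, c1, c2, amp, tau) = (1, −2e−5, −5e−9,
0.03, −150), about 5% total decay over 16 min; mean spikes per responder 2
(control) and 3 (knockdown) — the published figure states the knockdown
count is higher without printing values.

What the generator does *not* emulate: motion, focus drift, detector
nonlinearity, spatially correlated noise, biphasic spike shapes,
cell-to-cell signal crosstalk.  Passing tests therefore demonstrate
algorithmic correctness and statistical power under the stated conditions,
not robustness to every imaging artefact.

## Morphometry

Flow axis convention: +x of the image frame; downstream = increasing x.
Elongation factor = pixel extent along the flow axis / perpendicular
extent (projections, so perpendicular cells score below 1 — consistent
with elongation decreasing as cells turn).  Orientation is the acute angle
between the principal axis (second central moments) and the flow axis,
folded into [0°, 90°].  "Width" is the maximum perpendicular extent.
Border-touching cells are excluded and counted in the log.

Junction coverage thresholds the junction-protein image by Otsu and reports
the percentage of region pixels above threshold (covered) and below
(uncovered = gaps); the two sum to 100 exactly.

Protein polarization: intensity is summed perpendicular to the flow axis at
each station along it; background (5th percentile of the profile) is
subtracted and floored at zero; each side of the nucleus centre is rescaled
so the cell ends map to ±1.  The downstream fraction is the trapezoidal
area on positions > 0 over the total.  Note the degenerate case: a
perfectly uniform profile is annihilated by its own 5th-percentile
background; real profiles taper at the cell ends, which keeps the
background below the interior signal.  Repolarization kinetics fit
d(t) = d_inf − (d_inf − d0) exp(−t/τ) by least squares; the generator's
default τ is 30 min with ~116 cells averaged per time point, matching the
standard protocol.  Golgi polarity classifies the signed nucleus→organelle
projection with a 1 µm deadband (closed interval = unpolarized).

Nuclear-signal response versus shear fits pct = a ln(τ_w) + c; when the two
highest-shear points differ by < 2 percentage points their mean is reported
as the response plateau.

## Wall shear mapping

Velocity post-processing applies the acquisition's two bias corrections —
subtracting a no-flow reference image and averaging with a 180°-about-x
re-acquisition (rows flipped, v_y negated on re-registration; a directional
v_y bias common to both acquisitions cancels exactly) — then converts speed
to wall shear by the infinite-parallel-plate result τ_w = 6 µ Q / (b h²).
The measured in-plane speed is treated as the depth-averaged speed, so
Q = s̄ b h per voxel and the voxel width cancels: τ_w = 6 µ s̄ / h.  A
`profile="parabolic"` flag instead treats the measurement as the mid-plane
speed of a parabolic profile (1.5 × mean).  All shear math is CGS; SI
speeds are converted on load.  Default µ = 0.0078 dyn·s·cm⁻² (culture
medium at 37 °C), overridable.

## Problem sizes used in the shipped benchmarks

The acceptance suite runs the full two-condition pipeline at the published
group sizes (347 + 339 cells) for the group contrast, and at 300 cells per
group for parameter recovery; detector–oracle equivalence is exhaustive for
all 5-level traces up to length 6 plus 3000 random traces up to length 20;
bleach-fit recovery uses 100 seeded traces per scenario; repolarization
recovery uses 100 seeded repeats.  Recovered spike metrics are compared to
the ground truth of *detectable* spikes (duration ≥ 3 s, amplitude > 2 ×
true noise SD): at the reconstructed knockdown duration SD most drawn
spikes fall below the 3 s floor, so no detector implementing the published
rule could recover the unrestricted population means.  Two further rules
keep that comparison well-posed.  Cells whose true spikes occupy more than
25% of the flow phase are excluded from both sides: the noise estimator's
lower-75% truncation presumes spikes are a minority of samples, and beyond
that occupancy the median "baseline" sits on the spike plateau and the
threshold definition collapses (rare draws from the heavy-tailed knockdown
duration distribution reach >70% occupancy).  And each true spike is
matched to the union of detected runs overlapping it — durations and areas
of fragments are summed, amplitudes maximised — so one long event is never
double-counted.

## Known limitations

- Confluent monolayers under-segment (no watershed); per-cell traces then
  mix neighbouring cells.
- The additive detrend of a physically multiplicative bleach leaves a
  few-percent amplitude bias (quantified in the recovery tests).
- Fmin/Fmax are measured on raw terminal phases; residual bleaching between
  the flow phase's end and those measurements biases calibration slightly.
- The Mann–Whitney exact path is limited to n ≤ 8 per group without ties.
- `alpha >= 1` in the asymmetric loss is degenerate (zero-loss region); the
  selector avoids it, but a user fixing alpha there should expect a
  lower-envelope trend.
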