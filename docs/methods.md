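# Methods

## Scope and model

The package models a pattern-reversal fNIRS experiment: a radial
checkerboard reversing at 4 Hz is shown for 5 s ("S" trials), interleaved
pseudo-randomly with 0%-contrast mock presentations ("B" trials) that act
as a within-run blank control; 20 trials of each kind with 10 s
stimulus-off periods make a 10-minute block. Cortical activation is read
out as concentration changes of oxygenated (OHb), deoxygenated (DHb) and
total (THb = OHb + DHb) hemoglobin, obtained from two-wavelength
(760/850 nm) continuous-wave intensity recordings through the modified
Beer–Lambert law. The analysis summarizes each subject by the
blank-subtracted peak amplitude (and latency) of the block-averaged
response at the channel with the strongest THb response, and relates that
amplitude to Autism-Spectrum Quotient (AQ) scores by Spearman correlation
with Benjamini–Hochberg FDR correction.

## Stimulus geometry

Frames are normalized luminance in [0, 1]; gamma correction is assumed to
be applied downstream at display. The pixel↔degree mapping is linear
(pixels-per-degree from the full-screen visual angle). Rings have constant
radial width equal to the half-period 1/(2·0.33 cpd); the wedge count is
set so the tangential check width at half-maximal eccentricity matches the
radial width (the tangential layout is not uniquely determined by the
protocol, and responses do not depend on it). The default panel is a
32-inch 16:9 screen (69.8 × 39.3 cm) at 70 cm; both are configuration.

Edge blending computes a Canny mask of the (contrast-scaled) cartoon frame
with median-derived hysteresis thresholds (σ = 0.33, the "zero-parameter"
recipe) and swaps the checkerboard polarity at mask pixels, so output
luminances never leave the two checkerboard levels.

### Trial schedules

Schedules are seeded pseudo-random permutations of the 20 + 20 condition
labels, constrained to first- and second-order counterbalancing: each
condition is preceded (at lags one and two trials) equally often — within
one trial — by either condition. The HDR outlasts the 15-s trial spacing,
so without this constraint the response tail of preceding stimulus trials
leaks differentially into the stimulus- and blank-trial epochs and biases
the S − B contrast by up to several percent depending on the permutation;
history-balanced randomization is the standard remedy in event-related
designs. The constraint is symmetric under swapping the condition labels,
which keeps the probability of an S at every serial position exactly 1/2.

## Processing stream

Order: prune → optical density → detect motion → spline-correct →
wavelet-correct (targeted) → re-detect → band-pass → Beer–Lambert. All
parameters live in `PipelineConfig`; defaults: dRange 5·10⁻⁴–1.0 (detector
units), SNR ≥ 2, separations 0–45 mm, tMotion = tMask = 1 s,
STDEVthresh = 13, AMPthresh = 0.40 OD, spline p = 0.99, wavelet iqr = 0.80
(Daubechies-2, maximal decomposition level), band edges 0.01/0.50 Hz
(3rd-order Butterworth, forward–backward so the effective gain is |H|²),
partial pathlength factor 1.0 per wavelength, epoch window −2…20 s.

Decisions taken where the stream admits more than one reading:

* **Pruning** requires every criterion at *both* wavelengths.
* **Motion detection** applies the STDEV criterion to single-sample
  differences (threshold 13 × the SD of the difference series over
  artifact-free stretches, recomputed once) and the AMP criterion to the
  max–min excursion within any tMotion window; flags are dilated by
  ±tMask. Applying the STDEV threshold to windowed excursions instead
  would flag smooth physiological oscillations (e.g. a 0.01-OD, 0.1-Hz
  sinusoid exceeds 13 × the diff-SD over a 1-s window), which is clearly
  not intended behavior.
* **Spline correction** follows the movement-artifact-reduction scheme:
  within each flagged segment the series is replaced by its residual about
  a smoothing spline (abscissa in samples, penalty weight (1−p)/p, i.e.
  near-interpolating at p = 0.99), re-anchored to the preceding clean
  level; subsequent data are shifted to keep the series continuous.
  Segments shorter than four samples fall back to a mean shift.
* **Wavelet correction** zeroes detail coefficients outside
  [Q1 − 0.8·IQR, Q3 + 0.8·IQR] of their level's distribution. Applied to a
  whole channel this measurably attenuates block-design evoked responses
  (their detail coefficients are heavy-tailed per level because stimulus
  and mock epochs alternate), so the orchestrated stream applies it
  *targeted*: only on channels with detected motion, splicing the filtered
  samples into the flagged segments with a small edge offset. The
  standalone `wavelet_correct` operation retains the whole-series
  behavior; `wavelet_correct_targeted` is the hybrid used by
  `preprocess_recording`.
* **Residual artifacts** found by the second detection pass are not
  corrected again; trials whose epoch intersects them are dropped from the
  block average (per channel).
* **Extinction coefficients** are the Prahl compilation values at 760 nm
  (HbO₂ 586.0, HbR 1548.52 cm⁻¹ M⁻¹) and 850 nm (HbO₂ 1058.0, HbR
  691.32); with ppf = 1.0 the effective pathlength equals the
  source–detector separation, so concentration numbers are inflated by the
  missing differential-pathlength factor. This matches the quoted
  conversion convention; all recovery checks are relative to planted truth
  and do not depend on the absolute scale.

## Response extraction

Epochs are baseline-subtracted (mean over [−2, 0) s) per trial and
averaged per condition. Blank subtraction is sample-wise on the time
courses before peak extraction; a peak-minus-peak alternative is available
behind `peak_mode="peak"`. The peak search window is (0, 20] s; ties break
to the earliest sample, channel-selection ties to the lowest index. Best
channel is chosen on blank-subtracted THb amplitude (THb being the
headline chromophore). Latency is reported from the same blank-subtracted
trace; raw per-condition latencies are also in the metrics table.

## Probe montage

The default 22-channel occipital montage places 8 sources and 7 detectors
on a 3 × 5 grid (checkerboard type assignment); the 22 nearest-neighbour
pairs form the channels. Grid spacing is 3.5/3.0 cm for adult caps
(separations 30–35 mm, within the 20–44 mm hardware range) and 2.6/2.2 cm
for child caps (22–26 mm, within 22–30 mm). Coordinates are nominal
flat-cap positions centred on the occiput, not digitized 10-20 positions.

## Synthetic cohorts

The generator defines the study conditions for all tests:

* **HRF**: double gamma, peak 6 s, undershoot peak 16 s, undershoot ratio
  1/6; gamma shapes k = 13 (main lobe) and k = 17 (undershoot), giving a
  main lobe that has essentially decayed before the next trial while the
  undershoot stays shallow. Convolved with the 5-s boxcar and normalized
  to unit peak, so a subject's planted amplitude *is* the ideal recovered
  peak.
* **Amplitude link**: A_i = a − b·AQ_i + ε with per-cohort defaults —
  adult a = 3.75·10⁻⁶, b = 0 (no trait link, matching the absence of adult
  correlations), ε-SD 1.0·10⁻⁶; child a = 1.0·10⁻⁵, b = 1.25·10⁻⁷ per AQ
  point, ε-SD 1.1·10⁻⁶ (true Pearson ≈ −0.77, Spearman ≈ −0.67). Net
  child mean amplitude ≈ 1.6 × adult. Amplitudes are OHb peaks in the
  ppf = 1 concentration convention; evoked optical-density excursions are
  ~0.005–0.015 OD, the physically sensible range for strong full-field
  responses. DHb = −OHb/3 (configurable), so true THb = (2/3)·A_i.
* **AQ marginals**: truncated normals matching the reference cohorts
  (adult 15.1 ± 6.5, range 3–32; child 32.1 ± 10.7, range 17–49; the
  pre-truncation SD is widened by 1.25 to offset truncation shrinkage —
  the child range cannot support an SD of 10.7 under a unimodal law, so
  the simulated SD lands near 9). Subscales are a Dirichlet(2,…,2) split
  of the total, capped at the per-subscale maximum.
* **Noise** (OD units): cardiac 1.1 Hz sinusoid (amplitude 0.008),
  respiratory 0.25 Hz (0.002), both with 5% frequency jitter; a
  band-limited (0.02–0.2 Hz) Gaussian vasomotor background (RMS 0.0025);
  a random-walk drift (RMS 0.005); white noise (SD 0.002). The vasomotor
  band is Gaussian rather than sinusoidal because per-level wavelet
  statistics of real 1/f-like backgrounds are Gaussian, not arcsine.
* **Artifacts**: Poisson-scheduled spikes (0.3/min, 0.2–0.6 OD, 0.1-s
  width) and persistent baseline shifts (0.1/min, 0.1–0.3 OD), applied to
  both wavelengths of a random channel and logged in the ground truth.
* **Channels**: one best channel per subject carries gain 1; the others
  carry uniform gains in [0.2, 0.7], so best-channel selection is
  identifiable.
* **Determinism**: all randomness flows from one cohort seed through
  spawned per-subject streams; the same seed reproduces recordings bit
  for bit.

What the generator does *not* emulate: superficial/systemic physiology
shared across channels, optode-coupling spectral slopes, anatomical
forward modeling, serial correlation of AQ subscales, and session-level
nonstationarity. Passing tests therefore show the chain is correct and
well-calibrated under these idealized conditions, not that effect sizes
would transfer to human recordings.

## Measured performance under the default conditions

(Computed by the test suite, not asserted here.) Noise-free end-to-end
recovery of the planted THb amplitude is within 1% per subject; with
default noise and artifacts the relative RMSE at 20 trials is ~12%; the
planted negative THb–AQ association is recovered with the correct sign in
essentially all of 200 replicates at n = 19, while a b = 0 null keeps the
family-wise BH discovery rate at the nominal level.

Monte-Carlo suites run cohorts on a 5-channel subset of the montage; a
single replicate's conclusions do not depend on the channel count (the
best channel is planted), and the reduced montage keeps the replicate
count at 200.

## Known limitations

* The SNIRF writer emits a minimal conformant subset (one data block,
  per-wavelength measurement lists, 3-D probe positions); it reads its own
  files and simple externally produced ones, not every SNIRF variant.
* AQ item *keys* (direction and subscale membership) ship as editable
  configuration; the questionnaire text itself is copyrighted and not
  included, and translated editions may key items differently.
* The RM-ANOVA reports uncorrected degrees of freedom by default
  (Greenhouse–Geisser available via pingouin's `correction` argument).
* Isoluminant conversion rescales by a global gain; very dark frames with
  sparse bright pixels can exceed 1.0 after rescaling and are not clipped.
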