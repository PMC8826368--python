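# hemovis

Measuring visually evoked hemodynamic responses (HDR) in occipital cortex
with two-wavelength continuous-wave fNIRS, and relating their amplitude to
autistic traits in the general population.

The package implements the full experimental chain as a tested library:

* **Stimuli** — a full-field reversing radial checkerboard (0.33 cycles/deg,
  4 reversals/s, 90% contrast), an isoluminant grey-scale cartoon baseline,
  and auto-Canny edge-blend compositing so cartoon contours stay visible on
  top of the checkerboard; pseudo-randomized schedules interleaving 20
  stimulus (S) and 20 mock (B, 0%-contrast) trials of 5 s on / 10 s off.
* **Signal processing** — the standard fNIRS stream at 10.2 Hz over a
  22-channel occipital montage: optical density, channel pruning
  (intensity range, SNR ≥ 2, source–detector separation), motion-artifact
  detection (tMotion = tMask = 1 s, STDEVthresh = 13, AMPthresh = 0.40),
  spline interpolation (p = 0.99) and wavelet filtering (iqr = 0.80) for
  artifact correction, a 0.01–0.50 Hz zero-phase Butterworth band-pass, and
  the modified Beer–Lambert law

  ΔOD(λ) = [ε_HbO(λ)·ΔOHb + ε_HbR(λ)·ΔDHb] · d · ppf(λ),

  inverted over the (760, 850) nm pair to recover ΔOHb and ΔDHb, with
  THb = OHb + DHb.
* **Response metrics** — block averages over −2…20 s epochs, sample-wise
  blank subtraction (S − B), peak amplitude (max for THb/OHb, min for DHb)
  and latency, analyzed at the channel with the highest blank-subtracted
  THb amplitude per subject.
* **Statistics** — paired two-sided t-tests (S vs B), one-way
  repeated-measures ANOVA with generalized eta-squared, Spearman rank
  correlation between amplitudes and Autism-Spectrum Quotient (AQ) scores
  (total + five subscales) with Benjamini–Hochberg FDR correction, and OLS
  fits with 95% confidence bands.
* **Synthetic cohorts** — a generator planting a canonical double-gamma HDR
  with a negative amplitude–AQ link (A_i = a − b·AQ_i + ε), child > adult
  scaling, physiological noise (cardiac, respiratory, low-frequency
  vasomotor, drift) and motion artifacts, so every stage is testable
  end-to-end with known ground truth. The demographic/AQ tables of the
  reference cohorts (40 adults, 19 children) ship as packaged fixtures.
* **AQ scoring** — adult self-report (binary item scoring, total 0–50,
  risk threshold > 32) and child parent-report (0–3 Likert per item with
  reverse-scoring, total 0–150, threshold > 76).

## Worked example

Simulate a small two-cohort study and run the complete analysis:

```python
from hemovis import Study

results = Study({
    "seed": 7,
    "n_subjects": {"adult": 6, "child": 10},
    "conditions": ["L"],
    "n_channels": 8,
}).fit()

print(results.stats[results.stats.family == "stim_vs_blank"])
```

Output (child cohort; statistic is the paired t over subjects):

```
           family      cohort label  statistic            p  effect_size
    stim_vs_blank       child   THb  14.944609 1.164933e-07     6.957233
    stim_vs_blank       child   OHb  15.862276 6.936271e-08     7.520031
    stim_vs_blank       child   DHb -11.566320 1.052896e-06     4.846646
cohort_comparison child-adult   THb   3.428562 1.060663e-02     2.015499
```

The stimulus-driven signal separates from the blank for all three
chromophores (OHb rises, DHb dips, THb = OHb + DHb rises), and the child
cohort's amplitudes sit significantly above the adults'. The planted
negative amplitude–trait link surfaces in the correlation family:

```
     label  statistic        p  adjusted_p
  THb~AQ@L  -0.672727 0.033041    0.265960
```

i.e. Spearman ρ = −0.67 between blank-subtracted THb amplitude and total
AQ across the 10 simulated children: higher autistic-trait scores go with
weaker visually evoked THb responses.

A command-line entry point mirrors the library
(`hemovis stim|simulate|preprocess|extract|stats|run`), e.g.:

```bash
hemovis simulate --cohort child --n 19 --seed 1 --out-dir scratch/cohort
hemovis run --seed 7 --out-dir scratch/study
```

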