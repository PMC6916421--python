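# acmkit

Analysis toolkit for **ambulatory circadian monitoring (ACM)**: week-long,
free-living wrist recordings of skin temperature, motor activity, arm
position and environmental light, used in sleep medicine to tell apart
conditions that interviews often confound — delayed sleep phase disorder
(DSPD) versus sleep-onset insomnia, and insomnia subtypes versus healthy
variation.

The package covers the full chain:

1. **I/O and epoching** — read logger-style delimited text exports at their
   native rates (temperature 1/10 min; activity, tilt, light 1/30 s), align
   them on a common epoch grid trimmed to whole days, and build average
   24-h waveforms (mean ± SEM over days).
2. **TAP and sleep** — normalize the three body channels (temperature to its
   5th–95th percentile span and inverted; activity to its 95th percentile;
   tilt from horizontal 0 to vertical 1) and combine them into the
   activation variable TAP = (T′ + A′ + P′)/3 ∈ [0, 1]. Sleep is scored per
   epoch against a per-subject dynamic threshold (midpoint of the subject's
   TAP L5v and M10v) with 30-min median smoothing.
3. **Non-parametric circadian indexes** for any variable *x* with *n*
   samples, *p* per day, day-bin means x̄ₕ and grand mean x̄:
   - interdaily stability IS = n Σₕ(x̄ₕ − x̄)² / [p Σᵢ(xᵢ − x̄)²] ∈ [0, 1];
   - intradaily variability IV = n Σᵢ(xᵢ − xᵢ₋₁)² / [(n−1) Σᵢ(xᵢ − x̄)²]
     (≈0 for a sinusoid, ≈2 for white noise, 4 for a strict alternation);
   - M10/M5 and L10/L5 windows — the 10 or 5 consecutive hours of maximal /
     lowest values of the average day, their means (v) and midpoint clock
     times (h);
   - relative amplitude RA = (high − low)/(high + low), with the nocturnal
     M5 / diurnal L10 orientation for temperature and sleep (×10
     amplification for wrist temperature);
   - circadian function index CFI = [IS + (1 − min(IV, 2)/2) + RA]/3.
4. **Classification** — a published fixed decision tree on four attributes
   (TAP-L5h > 5:27 → {DSPD if TAP-M10h > 16:07 else onset insomnia}; else
   TAP-RA < 0.629 → maintenance insomnia; else sleep-CFI ≥ 0.852 → control,
   else mild insomnia), plus Fayyad–Irani MDL discretization, attribute
   scoring (information gain, ANOVA F, χ²), greedy tree induction, and
   10-fold cross-validated diagnostic metrics (sensitivity, precision,
   specificity, F1, FPR, one-vs-rest AUC).
5. **Synthetic cohorts** — a generative model of the five phenotypes
   (sleep schedules with jitter and awakenings, activity envelopes,
   first-order temperature dynamics, light exposure) so the whole pipeline
   is testable without clinical data.

## Worked example

```python
import acmkit as ak

rec = ak.generate_subject(ak.phenotype_presets()["dspd"], days=7, seed=3)
epoched, summaries = ak.analyze_subject(rec)
tap = summaries["tap"]
print(tap.l5h, tap.m10h, round(tap.RA, 3), round(summaries["sleep"].CFI, 3))
```

prints `440.0 1140.0 0.778 0.911`: this subject's mid-sleep marker
(TAP-L5h) is 7:20 — far past the 5:27 cut — and the activation midpoint
(TAP-M10h) 19:00 is past 16:07, so the fixed tree labels the subject DSPD:

```python
fv = ak.FeatureVector(rec.subject_id, tap.l5h, tap.m10h, tap.RA,
                      summaries["sleep"].CFI)
print(ak.classify_fixed_tree(fv))   # -> dspd
```

Running the whole default cohort (10 subjects per phenotype, 7 days) end
to end,

```sh
python examples/04_classify_cohort.py
```

prints

```
subjects analysed:      50
fixed-tree accuracy:    0.90
cross-validated (k=10): 0.90
```

i.e. the published tree recovers 90% of the generated phenotype labels.
The other scripts in `examples/` walk through simulation, TAP/sleep
estimation, the index battery, and tree induction, one capability each.
A thin CLI mirrors the pipeline: `acm run`, `acm simulate`,
`acm classify`, `acm validate` (see `acm --help`).

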