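# Methods

## Signals and epoching

An ACM recording carries four channels at native logger rates: distal
(wrist) skin temperature every 10 min, arm acceleration (m/s²), arm tilt
(degrees from horizontal) and environmental light (lux) every 30 s.
Distal skin temperature *rises* during sleep (peripheral vasodilation),
activity and upright posture fall; this opposition is what the TAP
combination exploits.

All channels are placed on one epoch grid (default 30 s) by averaging
samples within each epoch; channels coarser than the grid are carried
forward (step interpolation). Timestamps are naive local time, the day
boundary is local midnight, and leading/trailing partial days are
trimmed — the stability statistic is only defined over whole days. An
end-of-span remainder shorter than the 30-min fill tolerance is treated
as covered by the last sample rather than costing a day. Gaps are
bridged by forward fill up to 30 min; longer gaps stay missing, are
excluded from index sums, and may not exceed 20% of a channel.

Three time resolutions are used deliberately: the 30-s grid for TAP and
sleep scoring (native rate of the faster channels), 10-min bins for
average-day waveforms and window searches (minute-scale phase times),
and hourly bins for IS/IV (the classic choice for these statistics; both
bin lengths are configurable).

## TAP and sleep estimation

Temperature is normalized to the subject's own 5th–95th percentile span
(computed over the whole week, which stabilizes the anchors) and
inverted; activity is normalized to its 95th percentile; tilt maps
linearly from 0° (horizontal) to 90° (vertical). TAP is the unweighted
mean of the three normalized channels: the simplest rule consistent
with TAP = 0 exactly at minimal activation and 1 at maximal, and the
classifier depends only on orderings, not weights.

Sleep is binary per epoch: TAP below a per-subject threshold, the
midpoint of the subject's TAP L5v (nocturnal floor) and M10v (diurnal
plateau) from the average-day waveform. The midpoint of extremes is
scale-free, reproducible, and strictly inside the TAP range for any
non-constant signal. A 30-min circular median filter removes isolated
flips. The exact threshold algorithm used by the proprietary clinical
software is not public; this midpoint rule is this package's own
stand-in, and parameter-recovery tests show it agrees
with the generator's true sleep on ≥ 90% of epochs for unmasked
control-like subjects. Quiet rest in bed before sleep onset is scored
as sleep by any activation-threshold method; that is a real limitation
of the signal, not of the implementation, and is why per-epoch
agreement is only asserted for phenotypes without long sleep latency.

## Non-parametric indexes

IS reads the numerator of the published formula as the sum over the p
time-of-day bins (the reading under which a signal repeating exactly
across days attains IS = 1). IV is reported unclamped; it is capped at
its white-noise ceiling of 2 only inside the CFI so that all three CFI
components live on [0, 1]. Window searches scan every circular start
bin exhaustively; ties break to the earliest start from 00:00 (with a
small absolute tolerance so that exact ties are not decided by
floating-point accumulation order). Window midpoints are circular
minutes from midnight; averaging phases across subjects must use the
circular mean since delayed phenotypes straddle midnight.

RA orientation follows the variable: wake-peaking variables (activity,
position, TAP, light) contrast diurnal M10 against nocturnal L5;
sleep-peaking ones (temperature, sleep) contrast nocturnal M5 against
diurnal L10. Wrist-temperature RA is amplified ×10 (clamped at 1) for
reporting, because its physiological contrast is a few percent of its
mean; the CFI always uses the un-amplified value — the amplified one
would saturate the composite. Light is analysed as log10(lux + 1),
applied to the epoched series. Published cohort-mean CFI cells for
temperature, TAP, sleep and light are reproduced by this combination
rule to ±0.01; the activity column is not (0.495 computed vs 0.54
printed for controls) and its normalization is evidently different in a
way the source does not state, so activity CFI is computed but excluded
from consistency checks.

## Classification and validation

The fixed tree applies the published cuts literally: "later than" is
strict (a value exactly at 5:27 or 16:07 goes to the not-later branch),
RA < 0.629 strict, sleep-CFI ≥ 0.852 inclusive. Clock times are
linearized to minutes in [0, 1440); mid-sleep markers cluster around
03:00–08:00, far from the wrap-around, which is a documented limitation
rather than a handled case.

Discretization is Fayyad–Irani MDLP: candidate cuts at midpoints
between adjacent distinct values, a cut accepted when its information
gain (base-2, so "bits") exceeds the MDL coding cost, recursing on both
sides. Tree induction splits greedily on MDLP cuts by information gain,
ties broken by attribute order (L5h, M10h, RA, CFI) then lower cut;
leaves take the majority class with ties broken by class enumeration
order. Validation uses stratified 10-fold cross-validation (plain
shuffled folds with a warning when a class has fewer than k members),
one-vs-rest confusion counts accumulated over held-out folds, and the
printed formulas for sensitivity, precision (called "accuracy" or
predictive value in parts of the clinical literature — the name
`precision` is used here), specificity, F1 and false-positive rate;
zero denominators yield NaN rather than an exception. AUC is the
rank-statistic form (probability a positive outranks a negative, ties
½), identical to the trapezoidal area under the empirical ROC.

## Synthetic cohort model

The generator emulates what the pipeline measures, not physiology.
Per night, sleep onset/offset derive from Gaussian jitter of mid-sleep
time and duration around phenotype means; awakenings are Poisson counts
with exponential durations; a rest-in-bed state of Gaussian-jittered
latency precedes onset (low activity, near-horizontal tilt,
intermediate temperature). Wake activity is gamma-distributed around a
raised-cosine daytime envelope centred on the phenotype's activation
peak; temperature follows a square wave between wake and sleep levels
smoothed by a first-order response (30-min time constant) with Gaussian
measurement noise; light follows a solar arc while awake, near darkness
otherwise, with the DSPD phenotype additionally exposed to evening
artificial light until sleep onset. Masking options (afternoon naps,
device removal) exist but default to off for all phenotypes except the
mild-insomnia preset, whose irregular daytime dozing is part of the
phenotype itself (it is what degrades the sleep-rhythm robustness
without touching the nocturnal TAP trough).

Preset calibration targets the published class geometry: control
mid-sleep 3:54 with stable, high-amplitude rhythms; DSPD mid-sleep 6:48
with a late activation peak (18:07) and evening light; onset insomnia
with delayed mid-sleep (6:25), short sleep, hours of pre-onset bed rest
and a mid-afternoon activation peak; maintenance insomnia with seven
long awakenings per night (the fragmentation is calibrated only to put
mean TAP-RA below the 0.629 cut, since per-night awakening statistics
for the insomnia groups are not published); mild insomnia differing
from controls only in sleep-rhythm robustness. Two phase-marker biases
of the estimator are worth knowing when reading recovered phases: the
slow temperature response drags TAP-L5h ~30–45 min later than the
generated mid-sleep, and the post-wake temperature decay suppresses
morning TAP so that TAP-M10h cannot precede roughly wake time + 6 h.

What passing tests show — and what they do not: recovery of ≥ 80% of
generated labels by the fixed tree demonstrates that the pipeline
measures phase, amplitude and robustness consistently end to end; it
says nothing about real patients, whose within-class variance, masking
behaviour and comorbidity the generator does not attempt to model. The
synthetic subjects are more regular than real ones (IS near 0.9 versus
0.3–0.6 in clinical cohorts), so absolute index values are not
comparable to clinical tables — only their orderings against the tree
cuts are exercised.

## Problem sizes and numerics

Default experiment sizes: 10 subjects per phenotype, 7 recorded days,
30-s epochs (20,160 epochs per subject and channel); the white-noise IV
check uses 10⁵ samples; oracle-equivalence suites use 1,000 random
trials; induction recovery trains on 200 labelled vectors and evaluates
on 1,000 fresh ones. All randomness flows through numpy `default_rng`
seeds; per-subject seeds derive from the cohort seed via
`SeedSequence`, so cohorts are reproducible bitwise across runs and
platforms. Degenerate inputs fail loudly: constant signals have no IS,
IV or temperature normalization; all-zero activity has no reference
percentile; empty window sums and single-class scoring raise rather
than return silent zeros.
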