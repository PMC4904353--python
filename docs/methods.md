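# Methods notes

This note records the models and procedures implemented in `meao`, the
parameter defaults and why they were chosen, the behaviour of the synthetic
study generator, and the design decisions taken where more than one
reasonable convention exists.

## Time and data conventions

All times are seconds (float64).  Every recording interval is half-open
`[t0, t1)`; after windowing to the last part of a recording, time is
re-zeroed so `t0 = 0`.  The half-open convention is used consistently for
spike containment and for bin edges in network-spike detection, so a spike
exactly on a bin edge belongs to the bin to its right and no spike can be
double-counted.  Undefined statistics are IEEE NaN throughout; NaN is the
single missing-value encoding in electrode statistics and feature tables.

Channels are named `"<well>_<electrode>"` where wells are `A1`–`F8` on a
6 × 8 plate and electrodes carry row–column labels `11`–`44` for the 4 × 4
grid in each well (electrode index `e ∈ 1..16` maps row-major to the label).

## Windowing and plate screening

Analyses use the last 900 s of each recording; earlier activity is dropped
(equilibration after plate handling makes the tail the stable portion).  If a
recording is shorter than the requested window it is kept whole with a
warning rather than rejected, since truncated files are common in practice.

The per-age plate screen excludes a plate recording whose mean firing rate
(mean of per-electrode rates over the whole plate) exceeds
`mean + k·SD` (default k = 2) of the *other* recordings at the same age.  The
leave-one-out baseline was chosen over a pooled baseline because a strong
outlier inflates the pooled SD and can mask itself; with rounded published
thresholds the two readings tie, so the more sensitive one was adopted.  The
comparison is strict (`>`), and groups smaller than three are not screened.

An electrode is *active* when it has at least one spike in the analysis
window (`active_min_spikes = 1`, configurable).  No stricter default is
imposed because developmental data legitimately contain barely-active
electrodes and imposing an activity floor would bias early ages; a common
stricter alternative (≥ 5 spikes/min, i.e. 75 spikes per 15-minute window)
can be selected through the same parameter.

## Burst detection (MaxInterval)

Three phases, in order:

1. **Scan.**  A candidate burst opens at spike *i* when
   `ISI(i, i+1) ≤ max_begin_isi` and extends while following ISIs are
   ≤ `max_isi`.
2. **Merge.**  Consecutive candidates whose gap (last spike of one to first
   spike of the next) is `< min_ibi` are merged.
3. **Filter.**  Candidates with duration `< min_duration` (last minus first
   spike time, no padding) or fewer than `min_spikes` spikes are discarded.

Defaults: `max_isi = 0.25 s`, `max_begin_isi = 0.1 s`, `min_ibi = 0.8 s`,
`min_duration = 0.05 s`, `min_spikes = 6` — the parameter set conventional
for developing cortical cultures.  Merging *before* filtering follows the
behaviour documented for the Neuroexplorer implementation of the method; the
opposite order is available via `merge_order="filter_then_merge"` because
implementations in the wild disagree, and the choice is observable (two
sub-threshold runs separated by less than `min_ibi` survive under
merge-then-filter and vanish under filter-then-merge).  The detector is
validated against an independent, deliberately literal sequential reference
on randomized trains.

Statistics: the inter-burst interval is the gap from burst end to next burst
start (the same quantity `min_ibi` acts on).  All coefficients of variation
use the sample SD (n − 1); a CV needs at least two values, so the IBI CV
requires at least three bursts and the within-burst ISI CV at least two
pooled within-burst ISIs.  The within-burst firing rate is the mean over
bursts of `n_spikes / duration`.  An electrode is *bursting* when its burst
rate is ≥ 1 burst/min (inclusive).

## Network spikes and STTC

Network spikes: the window is divided into 3 ms half-open bins anchored at
`t0`; each bin is scored by the number of distinct electrodes with ≥ 1 spike
in it; an event is a maximal run of consecutive bins with count ≥ 5.  The
threshold is inclusive (a bin with exactly five active electrodes counts);
`strict_gt=True` selects the strict reading.  Onset/offset are the outer bin
edges of the run, duration their difference, and the peak the maximum
per-bin count within the run.  No refractory separation between events is
imposed — maximal runs are already disjoint by construction.

STTC with half-width Δt = 50 ms:

```
STTC = ½ [ (P₁ − T₂)/(1 − P₁T₂) + (P₂ − T₁)/(1 − P₂T₁) ]
```

`Pᵢ` is computed by binary search of each spike against the other train;
`Tᵢ` is the exact measure of the union of `±Δt` windows (overlaps counted
once), clipped at the interval boundaries, divided by the interval length.
The union computation is validated against a dense-grid coverage oracle.
When a term's denominator vanishes (`P·T = 1`) that term contributes 0,
following the reference implementation of the coefficient.  An empty train
yields NaN rather than an error, because silent electrodes are data, not
bugs.  The well-level correlation is the mean STTC over all unordered pairs
of active electrodes, skipping undefined pairs; it is NaN with fewer than
two active electrodes.

## Feature tables

Twelve features per well, in fixed order: `mfr`, `burst_rate`,
`burst_duration`, `frac_bursting_electrodes`, `within_burst_fr`,
`pct_spikes_in_bursts`, `cv_ibi`, `cv_within_isi`, `ns_rate`, `ns_duration`,
`ns_peak`, `mean_correlation`.  The firing rate is the median over active
electrodes; the six burst statistics are medians over bursting electrodes
(NaN when none burst); `frac_bursting_electrodes` is bursting/active; the
network-spike triple comes from the event detector (`ns_rate` is a true zero
when there are no events; the medians are then NaN).

A value is **zero only when its defining count is zero**; "undefined" is
always NaN.  The distinction matters because the plate-level aggregate is the
median of *nonzero*, non-missing well values — zeros are ignored there — so a
zero must always be a real measurement or an explicitly mandated fill.

The classification policy: wells with no bursts get `within_burst_fr` and
`burst_duration` set to 0; wells with no network spikes get `ns_duration`
and `ns_peak` set to 0; wells still missing `mean_correlation`, `cv_ibi` or
`cv_within_isi` (or any residual feature) are excluded.  Zero-fill is applied
before exclusion; since a burst-free well necessarily has undefined CVs, such
wells are always excluded regardless of the fill — the fill matters only for
wells that burst too little for some statistics but enough for the CVs.  Both
the fill counts and the excluded fraction are returned so the interaction is
auditable.  On synthetic study data the exclusions concentrate at the
youngest age, where many wells have no bursting electrode or fewer than two
active electrodes.

## PCA

Features are centred and by default scaled to unit variance (mixed units
otherwise let high-variance features dominate).  Constant features cannot be
standardised and are dropped with a warning.  Component signs are fixed so
each component's loading sum is ≥ 0, making results deterministic; for
developmental tables whose features all rise with age this orients PC1 as a
maturity axis.  Plate-level PCA drops plates with any missing median (the
count is visible to the caller via the table).  The PC1-versus-age
regression is ordinary least squares of the PC1 score on numeric DIV,
reporting the slope and its two-sided p-value.

## Classification

Protocol: random 2/3–1/3 train/test split, repeated 100 times, mean accuracy
reported; a split is redrawn if any age class is absent from either part.
Age (DIV ∈ {5, 7, 9, 12}) is treated as a categorical label, never a number.

*One-vs-one SVM.*  One binary radial-kernel SVM per unordered pair of
classes (six machines for four ages); every machine classifies every test
point and the majority vote wins.  Two-way vote ties are resolved by the
directly contested pairwise machine, any remaining tie by the smallest class
in sorted order.  Features are standardised with the training split's
mean/SD before fitting — radial kernels are scale-sensitive and the features
span four orders of magnitude in natural units.  Defaults γ = 0.1, C = 10;
a 10-fold stratified grid search (`tune_hyperparameters`) reproduces the
tuning on any table, with ties broken toward the smallest C, then smallest γ
(weaker regularisation pressure first).  The hand-rolled voting layer is
cross-checked against scikit-learn's built-in one-vs-one decision rule in
the test suite.

*Random forest.*  500 trees by default; feature importance is the mean
decrease in Gini impurity, averaged over the repetitions and then normalised
so the top feature scores 1.00.  Averaging over repetitions (rather than a
single fit) makes the ranking stable to the split draw.

*Curves.*  The feature-subset curve evaluates the SVM on the top-n features
of the importance ranking for n = 1…12; the pairwise-age curves restrict the
table to each pair of ages (binary chance = 50%) using the same global
ranking.

*Well subsampling.*  For each n and each trial, n wells are sampled without
replacement from every plate — by default the *same* wells across that
plate's recordings at all ages, emulating the assignment of wells to
experimental conditions on a physical plate (independent resampling per
recording is available).  The reduced table is re-run through the exclusion
policy and a single train/test split of the SVM; mean/min/max accuracy over
trials is reported per n.  At n = 48 the "subsample" is the full data, so
the trial-to-trial spread measures pure split variability.  At very small n
a class can lose all scorable rows; such classes are dropped from the trial
and all-but-degenerate trials record NaN, ignored in aggregation.

## Synthetic study generator

Shape: 16 plates × 48 wells × 16 electrodes at ages 5, 7, 9 and 12 DIV with
900 s windows; two recordings (one at DIV 7, one at DIV 12) are dropped by
default, giving 62 plate recordings and 2976 well recordings.

Per electrode, three superposed point processes: homogeneous Poisson tonic
firing; a renewal burst process (gamma inter-burst intervals with target CV,
bursts of ~Poisson-distributed size at a mean within-burst ISI with gamma
jitter); and well-level network events (Poisson in time) that recruit a
binomial subset of live electrodes, each firing a first spike at a ~2 ms
exponential latency plus a few extra spikes in a 10 ms envelope — the tight
alignment that makes events detectable in 3 ms bins.  Spikes are sorted,
clipped to the window and deduplicated at 1 µs (so ISIs are strictly
positive).  Electrodes are silent with an age-dependent probability.

Rates are modulated by hierarchical log-normal multipliers — per plate
(log-SD 0.15) and per well (log-SD 0.3) — drawn once and reused across a
plate's four ages, making plates and wells repeated measures, with
well-to-well variability larger than plate-to-plate variability as observed
in real culture data.  Defaults per age:

| DIV | rate (Hz) | bursts/min | spikes/burst | wb-ISI (s) | ISI jitter CV | IBI CV | events/min | participation | p(silent) |
|----:|----------:|-----------:|-------------:|-----------:|--------------:|-------:|-----------:|--------------:|----------:|
|   5 |      0.15 |        0.6 |            7 |      0.045 |          0.25 |   0.30 |       0.08 |          0.35 |      0.45 |
|   7 |      0.35 |        2.0 |            9 |      0.040 |          0.40 |   0.55 |       0.60 |          0.45 |      0.25 |
|   9 |      0.60 |        3.5 |           11 |      0.035 |          0.55 |   0.80 |       2.00 |          0.60 |      0.12 |
|  12 |      0.90 |        5.5 |           14 |      0.030 |          0.70 |   1.05 |       4.50 |          0.75 |      0.05 |

Every age-sensitive parameter is monotone in DIV, which reproduces the
qualitative developmental trajectories (rising firing, bursting, network
events, synchrony; rising ISI/IBI dispersion) and leaves the youngest age
sparse enough that a substantial fraction of DIV-5 wells is excluded by the
classification policy.  The magnitudes are generator choices pitched at
plausible values for developing cortical cultures on 16-electrode wells, not
estimates fitted to any recorded dataset.  Effect sizes are deliberately
large enough that the four ages are well separable (≥ 90% four-class
accuracy), so the generator can serve as a positive control;
`scaled_age_params(α)` shrinks every inter-age difference toward the
across-age mean, with α = 0 giving statistically identical ages for chance
calibration.

What the generator does **not** emulate: biophysical network dynamics
(no membrane or synapse model), non-stationarity within a recording,
electrode cross-talk or spike-sorting artefacts, realistic inter-feature
correlation beyond what the shared processes induce, and the particular
effect-size profile of any real dataset.  Passing tests therefore
demonstrate that the pipeline's statistics and protocols behave correctly
and recover known structure — not that any particular accuracy level will be
attained on recorded data.

Determinism: all randomness flows through `numpy` `SeedSequence`s keyed by a
single master seed and structural indices (plate, age, well), so output is
bit-reproducible and independent of generation order.

## Numerical choices and degenerate inputs

- Empty trains and silent wells propagate NaN, never raise.
- `ns_rate` is 0 (not NaN) with no events; event medians are NaN.
- Tie at the network-spike threshold counts as an event (inclusive ≥ 5).
- STTC terms with zero denominator contribute 0.
- Standardisation guards zero-SD features by leaving them centred (SD set
  to 1); PCA instead drops constant features, with a warning.
- Burst CVs with zero mean (cannot occur for positive gaps, but possible for
  pathological inputs) are NaN.
- The split retry loop bounds at 1000 draws before raising.

## Problem sizes used in the test suite

Unit tests run on hand-built wells and a reduced study (3 plates × 12
wells).  The end-to-end tests run the full default study (2976 wells) for
the shape accounting, trend, recovery and subsampling checks; classification
there uses 20 repetitions for the accuracy check and 100 repetitions for the
chance calibrations, and the subsampling comparison uses 100 trials at
n ∈ {4, 48}.  These sizes keep the whole suite to a few minutes on one core
while leaving the statistical assertions comfortably powered.

## Known limitations

- The HDF5 loader for externally produced files is best-effort: field names
  in the wild vary, and only the documented dialect is round-trip tested.
- The one-vs-one tie-break beyond two-way ties (lexicographic) is arbitrary;
  ties deeper than two-way are vanishingly rare on real-scale tables.
- Plate-level PCA and classification operate on medians and inherit their
  robustness but also their insensitivity to within-plate heterogeneity.
- The subsampling study reuses the already-extracted well features; it
  cannot model operator effects of actually plating fewer wells.
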