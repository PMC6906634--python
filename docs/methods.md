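# Methods

This note documents the models, numerical choices, and known limitations
of the package. It is written for a user deciding whether the defaults
fit their question and what a passing test suite does and does not show.

## Spike-train generation

**Gamma renewal.** ISIs are iid Gamma with shape `k = 1/CV²` and scale
`1/(rate·k)`, so the mean ISI is `1/rate` and the ISI coefficient of
variation equals the target CV; `CV = 1` recovers a Poisson process and
`CV = 0` (shape capped at 10⁶) a perfectly regular train. The train is
the cumulative sum of ISIs clipped to the recording window; the window
length, not the spike span, is the duration used for rates. The ordinary
(non-equilibrium) renewal start introduces a rate bias of order
`(CV²−1)/2` events per recording — below 0.01 Hz at the durations used —
so no equilibrium correction is applied.

**Independent CV2 control.** A renewal process ties CV2 to CV, but the
cerebellar-nuclei phenotype of interest is a CV2 shift at unchanged rate
and CV. The generator therefore modulates the gamma scale with a
symmetric two-state Markov chain: states carry reciprocal scale factors
`r` and `1/r` and switch with probability `q` per interval. Slow
switching (`q = 0.02`) moves variance into slow rate drift — global CV
rises while local CV2 stays near the within-state renewal value — and
per-interval alternation (`q = 1`) raises CV2 above it. Calibration is
deterministic: the global CV constraint fixes the within-state CV in
closed form via the scale moments, and the CV2 of a state pair
`E[2|aX − Y|/(aX + Y)]` for iid Gamma X, Y reduces (through
`U = X/(X+Y) ~ Beta(k,k)`) to a 1-D quadrature, leaving a bracketed
scalar root-find in `r`. Infeasible (CV, CV2) pairs raise an error that
reports the achievable CV2 range. Long-run empirical accuracy (tested):
rate within 1%, CV within 0.02, CV2 within 0.03 of target.

**Purkinje cells and the pause.** A Purkinje cell is an SS process plus
an independent CS process; simple spikes falling within
`(t_cs, t_cs + 20 ms]` of any complex spike are deleted (a spike exactly
coincident with a CS is treated as part of the CS). Since the published
rates are measured on pause-bearing trains, the SS process runs at
`rate/(1 − cs_rate·pause)` so the *observed* rate matches the
specification; the residual bias from overlapping pause windows is
second-order (< 0.05 Hz at 1.2 Hz CS). The generator imposes no absolute
refractory period, so a small number of sub-millisecond SS–SS or SS–CS
coincidences occur per recording; a threshold detector cannot resolve
these, which bounds round-trip spike-count agreement (see below).

**Cohorts.** A cohort spec holds one base process per condition and a map
of multiplicative group effects. Per-cell seeds are spawned from the
master seed via `numpy.random.SeedSequence`, making regeneration
bit-identical and cells independent. The built-in conditions mirror the
in vivo study design:

| condition | n/group | duration | control spec | mdx effect |
|---|---|---|---|---|
| awake Purkinje | 24 | 71 s | SS 85.3 Hz, CV 0.55; CS 1.2 Hz, CV 0.92 | SS rate ×0.81; CS CV ×0.83 |
| anesthetized Purkinje | 47 | 200 s | SS 30.8 Hz, CV 0.8; CS 0.6 Hz, CV 1.0 | SS rate ×0.87 |
| awake nuclear | 25 | 71 s | 60 Hz, CV 0.5, CV2 0.39 | CV2 ×1.19 |

Group means, effect ratios, and durations are the published values.
Numbers the source study never printed were fixed once at values typical
for these cell classes and are config-overridable: complex-spike rates
(1.2 Hz awake, 0.6 Hz anesthetized — awake recordings show more complex
spikes), awake SS CV 0.55, and the nuclear rate/CV (60 Hz, 0.5).
Anesthetized group sizes were 48/46 in the source design; the cohort type
carries a single per-group n, so 47/47 preserves the total N = 94.

**What the generator does not emulate.** Cells within a group are iid
draws from the group spec: there is no between-cell rate/CV dispersion,
no electrode drift, no multi-unit contamination, no behavioral
modulation. Consequently within-group SEMs are far smaller than in real
cohorts (measurement noise only), statistical power at the published
effect sizes is essentially 1, and published SEMs are not reproduced —
only group means and effect ratios are. Passing tests therefore validate
the *machinery* (calibration, sorting, inference arithmetic), not
field realism of cohort variance.

## Voltage traces and spike sorting

**Synthesis.** Analytic templates — a ~1.5 ms biphasic simple spike and a
~7 ms complex spike with three decaying spikelets at 45% of the main
trough — are added at ground-truth times (overlaps sum), Gaussian noise
is added, and the sum is band-pass filtered 0.3–13 kHz with a zero-phase
Butterworth (two second-order sections each direction, fourth-order
magnitude response), matching standard extracellular practice. The
default sampling rate is 30 kHz so the 13 kHz analog band edge is
representable (≥ 2× the upper edge). SNR is defined as simple-spike
trough amplitude over noise sigma.

**Detection.** Noise scale is the median absolute deviation / 0.6745;
events are negative-going excursions past `4.5σ`, trough-aligned, with a
1 ms refractory merge. Two amplitude floors — 35% of the 99.9th
percentile of |x| and 15% of its maximum — keep filter ringing and
rebound lobes out on clean traces where the MAD estimate collapses; both
sit far below any spike trough.

**Sorting.** The classifying feature is above-noise energy of the
*negative* signal in a window 1.5–6 ms after each trough: the squared
negative part (positive rebound lobes excluded by construction) is
smoothed at spikelet width, an empirical noise floor (median + 6 robust
sd of the spike-free background) subtracted, and averaged over the
window. Samples near other full-amplitude events are masked; an event
with another full-amplitude event inside its window cannot be complex
(true CS are followed only by small spikelets, because of the pause) and
is disqualified; small events shortly after a full-amplitude one are
spikelets and are excluded from the class split. The remaining features
are split by an Otsu threshold, accepted only if the high class is the
minority, clearly bimodal (Ashman's D ≥ 2), and carries real above-noise
energy; otherwise all events are labeled simple and a no-complex-spikes
flag is raised (the expected outcome for nuclear cells). Detected
spikelet crossings within 6 ms of a complex-spike trough are absorbed
into it. The pause-verification fraction — complex spikes whose next
simple spike comes more than 20 ms later — is reported as an independent
sanity check and equals 1.0 by construction on generator ground truth.

**Resolution limits.** Validated performance at SNR ≥ 8: simple-spike
recall and precision ≥ 0.99, complex-spike classification F1 ≥ 0.95,
with recall degrading monotonically as noise grows. Two ground-truth
events inside one refractory window merge into a single trough, and a
simple spike < 1 ms before a complex spike shifts the detected CS trough
by up to ~1 ms; tests therefore match simple spikes at 0.5 ms and
complex spikes at 1 ms tolerance (at ~1 Hz CS rates neighbor confusion
is impossible).

## Metrics conventions

CV uses the sample (n−1) standard deviation. CV and CV2 require ≥ 3
spikes (≥ 2 ISIs); below that they propagate as NaN and the group stage
drops the cell listwise, with counts reported. Rates divide by the
analyzed window length. Simple-spike ISIs spanning a complex spike are
*not* excluded by default (the formulas are applied literally to the
sorted train); an exclusion mode is available
(`exclude_cs_spanning=True`) since the convention is ambiguous in the
field.

## Group statistics

Wilk's λ comes from explicit within/between SSCP matrices; the two-group
exact-F identity is used for p-values (it reproduces published λ → p
pairs, e.g. λ = 0.9028 at N = 94 → P ≈ 0.026). Reports display the
conventional group df `(g−1, N−g)` alongside the exact-F df
`(p, N−p−1)`. The rank-sum z uses midranks, tie-corrected variance, and
no continuity correction (a flag enables it); its sign is positive when
the first (control) sample tends larger, and rendered reports print |z|
with a direction phrase since sign conventions vary. BH correction is
applied within each predictor's family of per-response p-values (m = 3)
at FDR 0.2. Median splits send values ≤ median to "low"; constant
covariates are skipped with a warning. `t_from_summary` generalizes the
equal-n SEM formula to pooled variance for unequal n; a zero pooled SEM
yields an infinite-t flag. Under the null the omnibus MANOVA gate runs
slightly above its nominal 5% (≈ 4–7% across seed batches) because the
CV/CV2 estimates are not exactly normal; this matches the tolerance used
in the acceptance checks and is inherent to the parametric omnibus on
these responses.

## Anatomy

Particles are 8-connected components (ImageJ's default connectivity)
with an optional minimum pixel size; area is foreground pixels times
(μm/px)². The published "per 50 μm" density normalization is ambiguous
between a length and an area reading; it is implemented literally as
`count / (reference_extent_um / 50)` with a caller-supplied reference
extent. Manual upstream steps (region outlining, thickness measurement)
are out of scope; their downstream numbers enter through
`t_from_summary`. A rejection-sampled non-overlapping-disk mask
generator provides ground truth for tests.

## Problem sizes

The test suite and the acceptance script use: 10⁴ s trains for
closed-form CV/CV2 limits; 5×10³ s for generator calibration; one 60 s
SNR-8 trace for sorting validation; 200 replicate cohorts (24 cells per
genotype, 71 s per cell) for decision-tree power and 1000 for the null
gate rate; 100+ random instances for each statistical oracle
equivalence. The full suite runs in well under a minute of simulation
time per component on one CPU.

## Known limitations

- The two-state CV2 mechanism is one of many processes consistent with a
  (rate, CV, CV2) triple; serial ISI correlations beyond lag ~1/q are
  not matched to any biological target.
- The energy-based CS classifier is validated on synthetic templates
  only; real recordings with bursty non-Purkinje units in the window
  would need the no-complex-spikes flag and pause verification consulted
  before trusting labels.
- MANOVA normality is approximate for CV/CV2 responses (slightly liberal
  gate, quantified above).
- With iid cells per group, pairwise tests can flag tiny systematic side
  effects (e.g. pause-induced CV shifts of < 0.01) that real between-cell
  variance would swamp; interpret simulated significance accordingly.
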