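# Methods

## The design under test

The package encodes a modified Latin square mixture design for ERCC spike-in
RNA controls.  Ninety-six catalogued controls (plus one extra control that is
not part of SRM 2374) are split into five subpools A–E; within a subpool the
controls sit on a relative-abundance ladder of 19 rungs, 2^0 … 2^16, 2^18 and
2^20, spanning a 2^20 dynamic range.  The subpools are mixed by volume into
four pools (labelled 12–15): subpools B–E rotate through the proportions
10/15/25/40 % as a cyclic Latin square, while subpool A is held at a constant
10 % — the "modification" — so it contributes a 1-to-1 component to every
comparison.  The six pairwise pool comparisons therefore realise nominal fold
changes of 4, 2.7, 2.5, 1.7, 1.6 and 1.5 (each in both directions) on top of
the ladder.

The packaged design table records three kinds of exclusion that the analysis
must honour: seven controls were synthesised as antisense RNA and produce no
signal on sense-probe assays; ERCC-00073 is omitted from all pools and serves
as a pure background probe on arrays; and ERCC-00113, though labelled subpool
E, behaves as a member of subpool C (a pool-preparation error), so the
analysis set re-labels it to C.

The per-control ladder positions were reconstructed by aligning the design
table's row order with the per-control log2 target abundances printed in the
outlier census, which cross-validates every subpool.  Under that alignment
all five subpools share the same 19-rung ladder for their SRM members; the
non-SRM control ERCC-00114 is assigned the one remaining printed value
(2^17).  The design loader validates all of this — ladder membership, the
2^20 span, the Latin square closure, the exclusion counts — before any
analysis runs.

## Dose-response models

**Centroids.**  Model fitting uses one point per detected control: the
average over the four pools of log2 nominal abundance against the average of
log2 signal.  A control missing from one or more pools (sequencing dropouts)
is flagged partial/undetected and excluded from fitting but retained for
reporting.  Averaging in log space weights the 2^20 range evenly.  Note a
consequence of centroid collapse: for a titrated control the mean of
log2 I over four abundances is not log2 I at their geometric mean, so even
noiseless data leave a small curvature residual (~0.03 log2 units at the
default parameters) where the response curve bends; single-abundance
(subpool A) centroids lie on the curve exactly.

**Hybridisation arrays** follow the Langmuir isotherm

    I = I_max · C / (K_d + C) + bg

with I the linear-scale intensity, C the relative abundance, I_max the
saturation intensity, K_d the dissociation constant (the abundance at which
background-corrected signal is half of I_max) and bg an additive background.
Only K_d is fit; I_max is anchored to the average linear signal of the most
abundant control in each of the four pools and bg to the average linear
signal of the omitted control.  Anchors are averaged in linear intensity
space (the model is linear-scale); log-space averaging is available for
sensitivity checks.  The deep-saturation anchor includes bg and sits ~0.2 %
below I_max + bg on the ladder; this costs well under 1 % in recovered K_d
(tested).  K_d minimises the sum of squared log2 residuals via bounded
scalar optimisation on log10 K_d; tests cross-check it against a dense grid
search.  The residual SD uses df = n − 1 (one fitted parameter).

**RNA-Seq** has no saturation; the model is a line of slope exactly 1 in
log2–log2 space with a fitted intercept.  The intercept has the closed form
mean(log2 signal − log2 abundance), asserted equal to the generic fit in
tests.  No bg term is used: the detection-status machinery (below) plays
that role at the bottom of the range.

**Outlier flags.**  A control is a response-curve outlier when its centroid's
absolute log2 residual exceeds t(1 − α/2, n − 1) × residual SD at the 99 %
level.  The interval construction is not uniquely determined by the
description it implements; this package defaults to this prediction-style
residual band (each control judged against the population spread), with a
mean-curve band (divided by √n) available via the `band` option.  On
10,000 Gaussian residuals the default flags ≈1 %, as it should.

## Linearity screens

Each titrated control's four points give an OLS slope in log2–log2 space
(m = 1 is ideal; slope is undefined for the constant subpool A) and a
monotonicity verdict via Spearman's rho computed by the classical formula
ρ = 1 − 6Σd²/(n(n²−1)) with midranks on ties.  ρ is compared to 1 exactly:
any tie or inversion marks the control non-monotonic.  This is deliberately
conservative — with n = 4 a formal test on ρ would be meaningless, so the
screen is purely descriptive and no multiple-testing correction applies.

**Linear region.**  The Langmuir model's expected log-log slope,
m(C) = (C/I)·I_max·K_d/(K_d + C)², rises from ~0 in the background-dominated
regime toward 1 and falls back to 0 in saturation.  Its two inflection
points — sign changes of the second difference of m(log2 C) on a 0.01-step
grid over the design ladder extended one decade each side, refined to
0.001 — bound the region where a proportional response can be expected.
With bg = 0 the low-side inflection does not exist and the region is
reported undefined (never fatal; the RNA-Seq path does not use it).  The
grid rule is cheap, reproducible and oracle-checkable; tests verify the
analytic slope against finite differences and the bounds against a
brute-force dense grid.

Non-monotonic controls inside the region are outliers; below it they only
delimit the detection floor and are listed separately as sub-range; on
RNA-Seq every non-monotonic control is flagged.  A control is placed by its
centroid abundance by default (`region_rule="any-point"` instead asks
whether any of its four abundances falls inside).

**Mis-assignment diagnosis.**  A non-monotonic control suspected of having
been mixed from the wrong subpool is re-scored under each candidate subpool's
proportion schedule: rank agreement (ρ) first, sum of squared residuals
against the platform fit as tie-breaker; all-equal signals return the
original assignment with a tie flag.  On simulated swaps at the default
noise level the true subpool is recovered in ≥95 % of runs.

## Ratio analysis

For any pool pair, M = log2 S_i − log2 S_j is plotted against
A = (log2 S_i + log2 S_j)/2 — the MA-plot convention; a config flag offers
the literal Bland-Altman abscissa (log2 of the mean linear signal) instead.
The Latin square fixes each control's nominal log2 ratio.  From a fitted
Langmuir model the whole expected (A, M) trajectory for a fold change f is
traced parametrically: M → 0 at both extremes (additive background and
saturation compression) and approaches log2 f only mid-range, never
exceeding it.  For counting platforms the expected M is flat at log2 f and
the low-count end is characterised empirically by its Poisson funnel.  The
recovery summary reports, per nominal fold, the median observed M and median
absolute error split by linear-region membership.

## Dynamic-range summary

Per pool sample, the minimum and maximum log2 signal over the detected
members of a subset (spike-ins, or an optional endogenous-background table)
are summarised as mean ± sample SD across the four samples; the range is the
difference of means with SDs combined in quadrature,
range_sd = √(min_sd² + max_sd²).  The quadrature rule is adopted because it
reproduces the published summary arithmetic for both the spike-in and
background rows of the bead-array platform.  Minima are per-sample over the
controls present in that sample (detected-only by construction).

## Synthetic data

The generator produces signal tables with the statistical structure the
analysis assumes, so every stage is testable without platform downloads.

*Arrays*: signal = log2(Langmuir intensity) + Gaussian noise — additive in
log2, i.e. multiplicative in intensity, matching the roughly constant
log-scale spread of hybridisation data.  Defaults: K_d = 10⁴ (mid-ladder),
I_max = 2^14, bg = 2^5, noise SD 0.1 log2 units, one replicate per pool.
The omitted and antisense controls emit background-level signal.  The
spike fraction (0.3 % wt/wt by default) rescales effective concentration
uniformly and is absorbed by K_d, so it is carried as metadata only.

*RNA-Seq*: per control and pool, reads are Poisson with mean proportional to
depth × molar abundance × transcript length.  The proportionality constant
is fixed across pools (normalisation by the cross-pool mean total weight)
because the real RPKM denominator is dominated by the constant background
library; pool-composition differences then appear as slightly different
spike read totals rather than as spurious between-pool ratio shifts.
Counts are reported as RPKM = count/(length_kb × reads_M) with a 0.01
reporting floor below which a value is missing; all-zero controls come out
undetected.  Default depth is 10⁶ spike-aligned reads per sample — the order
implied by a ~0.3 % wt/wt spike into a tens-of-millions-read library.
Transcript lengths default to a deterministic spread over 250–2000 nt,
typical of the control catalogue.  Antisense controls yield no reads against
a sense-strand reference.

*Anomalies*: a subpool mis-assignment map (with no explicit anomaly the
generator reproduces the as-prepared pools, in which ERCC-00113 really is a
subpool-C member), forced dropouts, and per-control log2 offsets mimicking
concentration errors.  Everything is a deterministic function of the config
seed.

What the generator does **not** emulate: probe-sequence-specific affinities
(every array control shares one K_d), analyte-specific processing biases,
non-uniform read coverage along transcripts, GC bias, overdispersion beyond
Poisson, and background (endogenous) transcript tables.  Passing tests
therefore demonstrate that the analysis recovers the structure it models —
not that any particular physical platform is free of the effects above.

## Numerical and reporting choices

- Nominal ratios are stored exact (rational) and rounded to one decimal only
  at the reporting layer (40/15 → 2.7).
- K_d optimisation: bounded scalar minimisation over log10 K_d ∈ [−4, 10],
  xatol 10⁻¹⁰; non-convergence raises with the bracketing diagnostics.
- Ties in the mis-assignment score fall back to the original assignment and
  are flagged.
- Report bundles (per-control table, fit sidecar, six ratio tables, range
  summary, outlier table, decision log) are pure functions of config and
  input, so reruns are byte-identical; floats in TSVs are written at 6
  significant digits.
- Problem sizes used by the test and acceptance layers: full design
  (89-control analysis set), 100 simulation seeds for stochastic recovery
  checks, 10,000 synthetic residuals for flag calibration, depth 10⁷ for
  high-depth sequencing checks.

## Known limitations

- With a single fitted parameter anchored by two experimentally derived
  constants, the Langmuir fit cannot absorb probe-to-probe affinity
  variation; real-platform residual SDs will be larger than the generator's.
- The linear-region rule depends on bg > 0; array data with background
  subtracted upstream will need a background override to obtain a lower
  bound.
- Spearman's rho over four points takes only 11 distinct values; the screen
  is a coarse classifier by construction.
- The dynamic-range summary assumes four samples; with a single sample all
  SDs are reported as 0 rather than undefined.
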