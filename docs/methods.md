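# Methods

## The calling procedure

RT-QuIC positivity calling reduces a plate of ThT fluorescence time series
(relative fluorescence units, one reading per well every 45 min) to one
binary decision per sample. The implementation follows the published
olfactory-swab/CSF protocol exactly, with every step a pure function so each
is testable in isolation.

**Baseline.** For each sample, the replicate wells are averaged pointwise
and the contiguous window of duration 10 h (all readings in the closed
interval [t, t+10]) with the smallest mean rfu is located; ties break to the
earliest window, and traces shorter than 10 h use the whole span and are
flagged. The window mean is subtracted from every replicate reading of that
sample; negative adjusted values are floored at 0 so normalized traces stay
in [0, 100]. The protocol's wording subtracts the baseline from the *mean*
trace; subtracting it from each replicate is the natural extension once
replicates are called individually, and the two agree on the mean exactly
(before flooring).

**Normalization scope.** The protocol normalizes "for each set of replicate
reactions" but applies a "20% of maximum" criterion, which is only
discriminative against a maximum *shared* across samples — a self-normalized
trace always peaks at 100% and a flat-noise well would trivially cross 20%
of its own noise maximum. The default is therefore `normalization_scope="run"`
(percent of the largest baseline-adjusted reading in the run); per-sample
scope is available for figure-style plots. An all-flat run has no
normalization maximum and is an error rather than a silent division.

**Thresholds.** Two coexisting definitions are implemented: the fixed 20%
line, and a noise threshold computed as mean + 3 SD (ddof = 1) of every
normalized reading with 15 ≤ t ≤ 17 h pooled across all samples ("all
samples" is implemented literally; the protocol does not say negatives
only). The default `threshold_mode="max_of_both"` requires a replicate to
clear both the noise floor and the 20% line; `percent_only` and `noise_only`
are selectable, and every run report echoes which threshold was effective.

**Crossing, lag, call.** A replicate crosses if any reading at t ≤ 80 h
(closed) is ≥ the effective threshold; its lag time is the time of the first
such reading, with no interpolation — the assay reads on a 45-min grid and
interpolating would fabricate sub-reading precision. A sample is positive
when at least 2 of its 4 replicates cross. Samples with k < 4 replicates
(swab tolerability varies, so 2–4 replicates occur in practice) are called
with the closest generalization, at least min(2, k) of k with k ≥ 2
required, and flagged in the output; k < 2 is an error. Boundary readings at
exactly 15, 17 or 80 h are included (closed intervals throughout).

**Group summaries.** Endpoint (mean across replicates of the last reading at
≤ 80 h) and lag averages are taken over positive samples only, matching how
positive-trace averages are plotted; the mean ± SD trace is computed
pointwise over the positive samples' replicate-mean traces.

## Diagnostic statistics

All closed forms are implemented directly (scipy supplies only distribution
primitives), and each is cross-checked in the test suite against an
independent route: exact-rational hypergeometric enumeration and
`scipy.stats.fisher_exact` for Fisher, `statsmodels` for McNemar, κ and the
Clopper–Pearson interval.

* Proportions: exact 95% Clopper–Pearson CIs from beta quantiles; printed
  percents use half-up integer rounding, the convention of clinical tables.
* Fisher (two-sided): sum of hypergeometric point probabilities ≤ the
  observed one, with a 1 + 1e-7 relative guard against floating-point ties.
* Cramér's V for 2×2: |ad − bc|/√(r₁r₂c₁c₂); zero margins are an error.
* Exact McNemar: p = min(1, 2·P(X ≤ min(b, c))), X ~ Binomial(b + c, ½);
  p = 1 when b + c = 0.
* Cohen's κ with the Fleiss–Cohen–Everitt asymptotic SE, CI clipped to
  [−1, 1]; degenerate margins (p_e = 1) define κ as 1 when agreement is
  perfect, else 0, and are flagged. For the reconstructed paired swab table
  (both+ 9, AN-only 9, MT-only 1, both− 4), κ = 0.19 reproduces the
  published point estimate, but the published 95% CI (0.00–0.49) is narrower
  than the asymptotic interval (−0.10 to 0.49) and its method is unstated;
  the asymptotic CI is reported and the discrepancy surfaced rather than
  matched by construction.
* OR-rule combination: a subject is combined-positive if either test is;
  subjects missing a test are excluded and counted.

## The synthetic generator

The generator emulates exactly the statistical structure the calling
procedure consumes; it makes no mechanistic claim about aggregation
kinetics.

* **Converting replicate**: baseline + P/(1 + exp(−k(t − t50))) + N(0, σ²)
  per reading, floored at 0 rfu. The plateau P is drawn per replicate as a
  Normal fraction of a fixed run-scale amplitude (default 10 000 rfu),
  clipped to [0.05, 1]; t50 is placed so the curve reaches 20% of its own
  plateau exactly at the drawn lag, making drawn and called lags directly
  comparable. Defaults: lag N(41, 4²) h for agger-nasi PD and N(47, 4²) h
  for middle-turbinate PD with plateaus 0.80 and 0.57 of the run maximum
  (the published group kinetics); growth rate k = 0.3 h⁻¹, giving the
  20→80%-of-plateau rise in ≈ 9 h as in typical positive traces; baseline
  800 rfu, reading noise σ = 20 rfu (≈ 0.2% of the run maximum, so the 3-SD
  noise floor sits far below the 20% line, as in a clean run).
* **Non-converting replicate**: flat baseline + noise.
* **Conversion structure**: replicates of a seeding sample convert
  independently with probability r back-solved from the target sample-level
  positivity under the ≥2-of-4 rule (the binomial tail is strictly
  increasing in r, so the solution is unique, though the replicate-level
  parameterization itself is one documented choice among several consistent
  with sample-level rates). Targets 0.84 / 0.45 / 0.10 give r ≈ 0.62 / 0.36 /
  0.14. Spontaneous conversion of non-seeders uses the same mechanism.
  Partial conversion is modelled at replicate level deliberately: it is what
  gives the 2-of-4 rule a decision boundary to exercise.
* **Lag truncation**: lag draws are rejected outside [20, 78] h so that
  converting replicates neither contaminate the 15–17 h noise window nor
  cross after the 80-h cutoff — the analytic ≥2-of-4 calibration assumes
  every converting replicate is countable. At the default σ ≤ 8 h these
  bounds are > 2.8 SD from every group mean, so the truncation shifts group
  moments negligibly.
* **Ground truth**: recorded before noise — per replicate, the conversion
  flag, the drawn lag, and the analytic first grid reading at which the
  noise-free, baseline-leak-corrected signal reaches 20% of the run-wide
  noise-free maximum (computed inside the generator with its own window
  scan, independent of the pipeline code). All randomness flows from one
  `numpy.random.default_rng(seed)` (PCG64), so identical configs reproduce
  traces bitwise.

**What the generator does not emulate** — plate-position effects,
evaporation, substrate lot variability, drifting baselines, correlated
replicate noise, and strain-dependent kinetics. Passing tests therefore
demonstrate that the decision procedure is implemented correctly and is
well-behaved (scale-invariant, threshold-monotone, exact on noiseless
input), not that the assay itself would achieve these accuracies on new
clinical material.

## Numerical and design notes

* The called lag is the drawn lag rounded *up* to the reading grid
  (+ ≈ 22 min in expectation) plus, under run-scope normalization, a
  plateau-dependent offset where 20%-of-run-max differs from
  20%-of-own-plateau. Recovery tests compare against these analytic
  expectations rather than the raw drawn mean.
* Baseline-window search is O(n) via cumulative sums with an exclusive
  `searchsorted` end; it is verified against an exhaustive per-start scan on
  traces up to 200 points.
* Fisher's test evaluates the full hypergeometric support vectorized; the
  exact-rational oracle in the tests uses `fractions.Fraction` arithmetic,
  exhaustively for all tables with total ≤ 12 and on random tables up to
  total 60.
* Problem sizes: the statistics layer runs on the printed counts (n ≤ 55)
  in microseconds; calibrated-rate recovery uses 2000 subjects per group
  (binomial SE ≈ 0.8 points on an 84% rate), the scale at which a 2.5-SE
  agreement check is informative, and completes in about half a minute.
* Trace CSV round-trips are written with 6 significant digits, which is
  loss-free for plate-reader-scale values (≤ 5 integer digits plus one
  decimal).

## Known limitations

* The published accuracy of 94% for CSF mixes PD and non-PD subjects whose
  pairing is only partially reported; the package computes accuracy from
  whatever complete paired data it is given and does not attempt to
  reconstruct that denominator.
* Pooled "overall" positivity across rounds is computed but labelled
  derived; the rounds are reported separately in the source tables.
* With replicate-level partial conversion and run-max normalization, the
  simulated group-mean endpoint of positive samples sits below the
  converting-well plateau (non-converting wells pull the 4-replicate average
  down); matching published endpoint averages and published positivity rates
  simultaneously would require sample-level conversion heterogeneity, which
  the generator deliberately does not use.
* No kinetic curve fitting (growth rates, sigmoid fits) beyond threshold
  crossing; no ROC analysis (the assay is binary by construction here).
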