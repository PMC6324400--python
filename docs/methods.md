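# Methods

This note documents the statistical procedure implemented by `icuref`, the
assumptions behind it, the design choices made where several readings were
defensible, and what the synthetic validation does and does not establish.

## Cohort definition

The unit of analysis is a patient's **first ICU stay**: one stay per
subject, the earliest `intime`, ties broken by smallest `stay_id`, so the
selection is deterministic under arbitrary row order. Stays younger than
`adult_age_min` (default 18 years) are removed; ages above 300 years are
treated as deidentification mask sentinels for very old patients and
retained as adults. Restricting to first stays keeps observations
independent — later stays of the same patient are correlated with the
first and are discarded entirely, including their lab events.

**Worst first-day values.** For each stay and panel test, events inside the
half-open window `[intime, intime + window_hours)` (default 24 h) are
reduced to the clinical extreme(s) configured for the test: the minimum for
analytes whose dangerous direction is low (albumin, ionized calcium,
hemoglobin, platelets), the maximum where it is high (lactate, bilirubin),
and both for analytes dangerous in either direction (electrolytes, renal
markers, glucose, white cells). Events carrying a `stay_id` are matched by
it; events without one fall back to subject + time window. A stay with no
in-window event for a test contributes nothing to that test and everything
to the others — missingness is handled per test, never by excluding the
patient. Whether the clinical "first day" should include a pre-admission
buffer is a judgement call; the window start is `intime` by default and
`window_hours` is configurable.

**Outcome groups.** Stays ending in ICU death form `DIED_WORST`
(death after ICU discharge does not count — stratification is on ICU
mortality). Survivors are ranked by `(los_days, stay_id)` ascending and
rank *r* of *n* maps to quartile ⌈4r/n⌉: `Q1_BEST` holds the shortest
stays. This rule is exactly reproducible (the tie-break makes it
deterministic), and its quartile sizes differ pairwise by at most one;
with 35 515 survivors it yields a first quartile of exactly 8878. Quartile
cut-points are computed on all selected stays, before any per-test
missingness exclusion. Fewer than four survivors is an error rather than a
silent merge.

## Reference intervals as distributions

A hospital reference interval `(L, U)` is the central 95% of a healthy
population. To compare distributions rather than ranges, the interval is
instantiated as the normal distribution with

    mean = (L + U) / 2,    sd = (U − L) / (2 z),   z = Φ⁻¹(0.975) ≈ 1.959964

whose central 95% reproduces `(L, U)` to machine precision (asserted to
1e-9). A normal healthy cohort is the canonical reading of how reference
intervals are constructed; it is an assumption — the true healthy-
population shape and SD are not observable from the interval alone, and
every reference-relative SMD inherits it. For strictly positive analytes a
log-normal instantiation (same mapping on the log scale) is available; the
default stays normal, with the density clipped at zero and renormalized on
the evaluation grid when the interval sits close enough to zero for mass to
spill below it (e.g. lactate, 0.5–2.0 mmol/L).

By default the reference side of OVL/SMD/Wilcoxon uses this distribution
*analytically* — exact density on the grid, exact mean — which removes one
layer of Monte-Carlo noise. A sampled mode (`reference_mode="sampled"`,
`reference_n` seeded draws) exists for parity checks and agrees with the
analytic route to sampling error.

## Divergence statistics

**KDE.** Gaussian kernel with the Silverman rule-of-thumb bandwidth
`h = 0.9 · min(s, IQR/1.34) · n^(−1/5)` (configurable: Scott's rule, a
fixed h, or a callable). The density is evaluated on 512 evenly spaced
points spanning `[min − 3h, max + 3h]`, clipped at zero for non-negative
analytes, and renormalized to integrate to one on the grid — so truncation
never produces spurious sub-zero mass.

**OVL.** `∫ min(f₁, f₂)` by trapezoid on the union of the two grids, each
density linearly interpolated and zero outside its own grid; clipped to
[0, 1]. For two equal-variance normals the exact value is `2Φ(−|Δμ|/2σ)`,
which serves as the closed-form oracle: at n = 50 000 the KDE path matches
it to well within 0.02 across separations d ∈ {0, 0.5, 1, 2}.

**SMD.** Cohen's d with the classic pooled SD
`√(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2))` between two samples. Against the
analytic reference the pooled SD is the balanced form `√((s² + sd_ref²)/2)`
— the equal-group-size limit — so the analytic and sampled routes agree
regardless of how many reference draws the sampled route uses. Effect
bands on |SMD|: < 0.2 small, 0.2–0.8 moderate, > 0.8 large. Sign
convention: ICU cohort minus reference, so depressed analytes (albumin)
are negative.

**Trimmed central intervals.** The central 95% of a cohort excludes 2.5%
per tail using linear-interpolation quantiles on the order statistics
(position `1 + p(n−1)`); the convention matters because interval endpoints
depend on it, so it is fixed and stated.

**Hypothesis tests.** One-sample Wilcoxon signed-rank of each cohort
against the reference mean (zeros dropped, mid-ranks for ties, exact
distribution for n ≤ 25 without ties, tie-corrected normal approximation
otherwise; two-sided). Kruskal-Wallis with tie correction for continuous
group comparisons, Pearson χ² without continuity correction for
categoricals. p-values are reported per test without multiple-testing
correction — they describe each comparison, not a family-wise claim.

## Outcome profiles

Before binning, extreme values totalling `trim_fraction` (default 5%,
split 2.5% per tail — matching the trimming convention used for the
intervals; asymmetric trimming is a config option) are excluded: bins out
in the tails would hold too few stays for stable proportions. The kept
range is divided into `n_bins = 20` equal-width bins (the final bin
right-closed); per bin, the counts of the five outcome groups are tallied
and normalized. Empty bins are reported with zero counts and null
proportions rather than dropped, keeping bin edges stable across analytes.
Two invariants hold by construction and are asserted in tests: every
non-empty bin's proportions sum to 1 (to 1e-9), and the count-weighted
average of the rows equals the marginal group shares among kept stays.
Fixed bins (not a sliding window) were chosen for auditability; no
smoothing or per-bin confidence bands are applied.

## Synthetic cohort generator

The generator emulates the structural features of a deidentified
critical-care export that the pipeline must handle:

- **Outcomes**: ICU death drawn Bernoulli with `death_probability = 0.08`
  (a typical adult ICU mortality of ~8%); survivors get the same LOS
  family as non-survivors.
- **LOS**: log-normal, median 2 days, log-SD 0.9 — right-skewed with a
  realistic tail of week-long stays.
- **Lab values**: per analyte, a baseline normal or log-normal
  distribution; each outcome group's location is shifted by a configured
  multiple of the scale, so the configured shift *is* the true SMD of that
  group versus baseline (equal variances within an analyte — a modelling
  simplification, not a claim about real ICU data). The six default
  analytes mimic the qualitative ICU pattern: albumin depressed (most in
  non-survivors), lactate and creatinine elevated and skewed, hemoglobin
  mildly depressed, sodium nearly centred, glucose elevated; albumin is
  missing for 59% of patients and lactate for 40%, the rest nearly
  universal, mirroring how often these tests are actually ordered.
- **Events**: each measured patient receives `1 + Poisson(mean − 1)`
  first-day measurements (default mean 3) at uniform times in the window.
- **Decoys**: 12% of survivors get a later second stay whose events are
  drawn 2.5 scales off baseline — conspicuous, so any leakage of non-first
  stays into the analysis shows up as a location artefact.
- **Ages**: uniform 18–89, with an option to mask a fraction to a > 300
  sentinel as deidentification does for very old patients.

Determinism: every analyte draws from an RNG substream keyed by
`(seed, test_id)` (CRC-32 of the test id mixed into the seed sequence), so
adding an analyte never perturbs another's draws, and identical config +
seed reproduces the output tables byte for byte.

What passing on synthetic data shows — and does not. The generator has no
physiological time-series dynamics, no inter-analyte correlation, no
informative ordering (missingness is independent of severity), and
group-conditional distributions are clean location shifts. Recovery of
configured SMDs, closed-form OVLs and monotone mortality trends therefore
validates the *estimators and plumbing*, not the clinical findings on any
real cohort; real-data conclusions require a real export.

## Numerical and interface choices

- Worst-of-k extraction shifts each group's location relative to the raw
  measurement distribution (an order-statistic effect, identical across
  groups); reference-relative SMDs on the synthetic cohort are therefore
  larger in magnitude than the configured measurement-level shifts, while
  their ordering across groups is preserved — the ordering, not the
  magnitude, is the validated property.
- Problem sizes in the test-suite and acceptance runs (cohorts of
  1 000–4 000 patients, 50 000-draw OVL checks, 10 000-per-group SMD
  checks, 1 000 null replicates) were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably inside each check's tolerance.
- The pipeline manifest hashes the resolved scientific configuration
  (panel, windows, trims, seeds — not output paths), so identical runs into
  different directories produce identical bytes.
- An empty panel, degenerate reference interval, non-positive scale,
  empty stay table, fewer than four survivors, non-numeric lab value, or a
  worst-value record referencing an unknown stay each raise a typed error
  (`ConfigurationError` / `InputDataError`) naming the offending input; a
  panel test with no events at all warns and is simply absent from the
  outputs, with its 100% missingness recorded in the manifest.
- The CLI (`icuref synth|cohort|divergence|profiles|run`) is a thin layer
  over `RunConfig`/`run_pipeline`; plots (PNG) are optional and excluded
  from the byte-identical reproducibility guarantee.

## Known limitations

- Reference-relative SMDs depend on the normal instantiation of the
  interval; a heavier-tailed healthy population would change them.
- OVL is estimated from KDEs; very small cohort slices (< 6 values) are
  skipped with a warning rather than estimated badly.
- No bootstrap confidence intervals for OVL, no censoring-aware density
  estimation, no unit conversion (panel units must match event units), and
  no age/sex-partitioned reference intervals.
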