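# Methods

## Model and procedure

Let D be the time to perform one nerve block, measured from patient entry
into the block room to intrathecal injection. Blocks in a series are
treated as independent and identically distributed, with no gaps between
patients; the total for k sequential blocks by one anesthesiologist is
T_k = D₁ + … + D_k. All quantities are in minutes.

Because single-block times fit none of the duration families historically
used for anesthesia times, prediction limits are computed from the
empirical distribution. Given an observed sample d₁…d_N, the engine draws
k indices uniformly with replacement N_sims times (default 100,000;
Mersenne Twister via `numpy.random.MT19937`) and sums the selected
durations. The 100p% upper prediction limit UPL_p(k) is the p-th
percentile of the simulated totals. With N_sims this large the percentile
of the simulated distribution is an upper prediction limit for a future
series in the usual OR-management sense.

Parallel staffing uses a Bonferroni argument: if m anesthesiologists each
perform ⌈n/m⌉ blocks, planning each at coverage P* = 1 − (1 − P)/m keeps
the joint probability that all finish within the planned time at least P.
For m = 2 and P = 0.90, P* = 0.95. The adjustment is conservative
(independence would give 1 − √(1−P) ≈ 0.9487 for m = 2); m > 2 is
supported by the same formula. Uneven series sizes are planned on the
largest per-person load.

## Quantile rule

UPLs use the nearest-rank rule: the ⌈p·n⌉-th order statistic. It is
conservative (never below the interpolated value), exact on discrete
distributions, and at n = 100,000 differs from linear interpolation by a
negligible amount; `quantile_rule="linear"` is available. Descriptive
summaries of raw samples (`summarize`) use ordinary linear interpolation,
as they describe data rather than set planning limits.

## Cohort cleaning

Raw records carry four timestamps (block-room entry, intrathecal
injection, block-room exit, OR entry). Five rules remove internally
inconsistent records: injection missing; injection before entry; injection
after exit; injection after OR entry; exit after OR entry. Comparisons are
strict — boundary equality (e.g. injection at the entry minute) is
legitimate charting, not an inconsistency. Every rule is evaluated on
every record so multi-criteria tallies are exact. Note the rules are
logically coupled when all four timestamps are present: "injection after
OR entry" cannot hold alone (it forces "after exit" or "exit after OR
entry"), and "after exit" plus "exit after OR entry" force "after OR
entry". The synthetic violation injector honors these implications and
rejects infeasible specifications.

## Synthetic duration generator

The generator defines the study conditions; its defaults are the published
cohort sizes and summary statistics (spinal: n = 8,462, median 8,
mean 8.8, SD 0.06·√8462 ≈ 5.52, q80 11, q90 14.4; CSE: n = 2,916,
median 12, mean 12.8, SD 0.12·√2916 = 6.48, q80 17, q90 21).

Family: a two-component lognormal mixture,
F(x) = w·Φ((ln x − μ₁)/σ₁) + (1−w)·Φ((ln x − μ₂)/σ₂). A single lognormal
matched to the spinal median and q90 implies SD ≈ 4.3, well below the
published ≈ 5.5, so a heavier-tailed second component is required; the
mixture is the simplest positive, right-skewed family with enough freedom
to satisfy all five targets.

Calibration minimizes the summed squared mismatch between the mixture's
(mean, SD, median, q80, q90) and the targets — moments analytically,
quantiles by geometric bisection of the CDF — with Nelder–Mead from four
deterministic starting shapes, rejecting near-degenerate components
(σ bounded to (0.02, 2)). The fit is then verified on a seeded
100,000-draw sample: every realized statistic must be within
tol = 0.3 min of its target or calibration raises. The spinal targets are
met to ~10⁻⁸; the CSE targets sit at the family's boundary and the best
non-degenerate fit leaves the mean +0.19 min and median −0.09 min (inside
tol). Closer CSE fits exist only by letting one component collapse toward
a point mass, which we rejected as unrealistic synthetic data.

The tail above q90 is unconstrained by the published statistics; the
calibrated spinal mixture puts the single-block 95th percentile near
18.6 min. Quantities that lean on the extreme tail (95% UPLs, hence
parallel plans) therefore carry extra model uncertainty of roughly one
minute.

Cohort fixtures wrap sampled durations in timestamps on a 1-second grid
(entry < injection < exit < OR entry for clean records) and corrupt a
seeded random subset so each designated record triggers exactly its
assigned rule set. The default violation structure uses the published
per-rule tallies (235, 156, 174, 117, 73) with 126 doubly-flagged records,
yielding exactly 629 unique exclusions out of 9,091 and 8,462 retained.
The generator does not model provider effects, time-of-day or learning
trends, between-patient gaps, or charting granularity coarser than one
second — so passing tests demonstrate the engine's correctness on
distributionally matched data, not the behavior of any particular
hospital's records.

## Fitting and comparison

`fit_family` computes maximum-likelihood fits (location fixed at zero for
the positive-support families) via `scipy.stats` and screens each with a
Kolmogorov–Smirnov test against the fitted distribution. Using estimated
parameters makes the KS p-values anti-conservative (too large), so
rejections are trustworthy while non-rejections are weak evidence; no
Lilliefors-type correction is applied, matching standard screening
practice for this decision ("is any classic family usable?" — no). Zero
durations, possible boundary artifacts of minute-level charting, are
dropped from log/gamma/Weibull fits with a logged warning.

Group comparison uses the Mann–Whitney U (unpaired rank-sum) test:
mid-ranks with tie-corrected normal approximation for large samples, and
full enumeration of all C(n, n_a) relabelings for n_a + n_b ≤ 12. The
exact two-sided p is the permutation probability of a U at least as far
from n_a·n_b/2 as observed — tie-aware, and identical to the doubled
one-sided p when the permutation distribution is symmetric.

## Numerical and design choices

- Independent resampling per table row (fresh substream per k, spawned
  from one seed), keeping rows independent; identical configuration gives
  bit-identical totals.
- The convergence diagnostic compares a UPL from the full stream with the
  same UPL from its first 90% of totals; because the subset is a prefix,
  the two estimates are positively correlated and the difference isolates
  the marginal value of the extra simulations. On continuous duration
  data the 95% UPL difference at k ≤ 9 is typically a few seconds; it
  collapses to ~0 only when durations sit on a coarse (minute) grid, as
  quantile estimates then snap to grid points.
- The exact-convolution oracle (`exact_totals_quantile`) enumerates the
  k-fold sum distribution of a small discrete distribution (guard: ≤ 10⁶
  outcomes) and anchors the resampling engine in tests.
- Rendered tables round half-up to whole minutes (8.8 → 9, 14.4 → 14);
  all internal values keep full precision, which is why printed increments
  (e.g. UPL₀.₉(2) − UPL₀.₉(1) ≈ 12.2) need not match differences of
  rounded table entries.
- Timestamps are ISO 8601 in one local timezone with no midnight-crossing
  logic (morning block-room workflow); a record's timestamps must span
  less than one calendar day.
- Simulation sizes in the shipped tests and acceptance script are the
  defaults above (100,000 resamples, k ≤ 9; 10⁶ only for the oracle
  agreement check), chosen to keep the full suite in the low minutes on
  one CPU.

## Known limitations

- The synthetic generator reproduces five summary statistics, not a real
  duration distribution; tail behavior above q90 is extrapolated by the
  mixture form.
- The iid/no-gap assumption means planned times are briefest-case: real
  series incur transition gaps, consent, positioning and staffing
  frictions, so real lead times should exceed these estimates.
- The Bonferroni parallel adjustment ignores that parallel staff draw from
  the same block-room resources (assistance, rooms), which could correlate
  their series in practice.
- The published multi-criteria exclusion count (190) is arithmetically
  inconsistent with the published per-rule and unique totals; the fixture
  reproduces the unique total exactly and the per-rule tallies, not the
  printed overlap count.
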