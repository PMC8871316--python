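# Methods

## Classification model

Every solid pulmonary nodule with software-measured maximal diameter of at
least 3 mm (inclusive) at baseline enters the analysis. Two volumes are
attached to each nodule:

- **MV**, the measured volume from semi-automated segmentation (an input to
  this package, never computed from images);
- **EV** = (π/6)·D³, the volume of the sphere on the maximal diameter D.
  Only the maximal diameter is used; a mean-diameter variant is deliberately
  not implemented.

The LDCT outcome maps volume to {negative < indeterminate < positive} with
cut-offs 113 and 260 mm³. The printed band "113–260" carries no bracket
convention, so the indeterminate band is taken **closed on both ends**,
consistent with the strict outer inequalities (< 113, > 260); the same
convention gives [400, 600] days for the indeterminate VDT band. Both are
configurable in `ScreeningThresholds`.

VDT = ln2·ΔT / ln(V₂/V₁) between baseline and first recall. The EV-based
VDT uses EV at *both* timepoints, simulating a purely diameter-driven
program. Stable nodules (V₂ = V₁) have no finite doubling time and are
flagged undefined; shrinking nodules have negative VDT. How these are
categorised is genuinely open — screening datasets clearly contain negative
VDTs — so the package exposes a switch:

- `shrinking_vdt_rule="benign"` (default): shrinkage is not growth, hence
  probably benign;
- `"literal"`: the band edge "< 400 days" is applied literally, so negative
  VDTs are probably malignant. This reading is what makes the
  probably-malignant column dominate observed screening cross-tabs, since
  measurement noise alone shrinks roughly half of all stable nodules.

Undefined VDT is probably benign under either rule.

## Units

mm, mm³ and days throughout. Follow-up intervals are quoted in months
(36 / 12 / 3 by severity; the positive-category interval is not printed in
the source tables and defaults to 3 months, configurable) and converted at
1 month = 30.44 days where a day axis is needed. The recall-burden
simulator schedules scans at t = i, 2i, … up to and including the horizon,
counts them, and excludes the baseline scan; only the interval-to-horizon
ratio matters, so the month/day conversion does not affect counts.

## Cohort analyses

**PN-based**: every eligible baseline nodule is one item. **Screenee-based**:
one item per screenee via a dominant nodule. The dominance criterion is not
specified by the protocol; the default is the largest MV at baseline, with
ties broken by larger maximal diameter and then lexicographically smallest
nodule id, and two alternatives are provided (`by_EV`; `worst_category`,
which takes each measure's most severe category over all of the screenee's
nodules, possibly from different nodules). VDT denominators exclude
nodules/screenees without a re-measured follow-up volume, which is why the
VDT tables are smaller than the LDCT tables (2311 < 2715 PN-based,
1347 < 1583 screenee-based).

The severity-shift fraction is, among discordant items, the share whose EV
category demands a shorter follow-up: above-diagonal cells for the LDCT
ordering (severity rises with index), below-diagonal for the VDT ordering
(probably-malignant is listed first).

## Weighted kappa

Implemented from the definitional formulas (observed and expected weighted
agreement from the table and its marginals). Three schemes: identity
(unweighted), linear (Cicchetti–Allison) and quadratic (Fleiss–Cohen). The
scheme behind the published agreement values was not stated; brute-force
comparison across all four packaged tables (in the test suite) shows
quadratic reproduces all four values at 2 d.p. (0.49, 0.37, 0.52, 0.34)
while linear (0.38, 0.36, 0.40, 0.33) and unweighted do not, so quadratic
is the default. Reported kappas are rounded half-up to 2 d.p.; full
precision is kept in machine-readable output. No standard errors or
confidence intervals are computed. The implementation is cross-checked in
tests against statsmodels and against a per-item brute-force oracle that
never builds a table.

## Synthetic cohort generator

No generative model is published for these data; the generator's
distributions are calibration choices that approximate the printed cohort
shape (1583 screenees, 2715 nodules, MV marginals ≈ 81/12/7%
negative/indeterminate/positive), not estimates of the trial's true joint
distribution. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_screenees | 1583 | screenees with ≥ 1 eligible nodule |
| nodules_per_screenee | zero-truncated Poisson, mean 2715/1583 ≈ 1.715 | rate solved numerically |
| MV | lognormal, median 35 mm³, log-sd 1.3 | baseline measured volume |
| shape ratio s = MV/EV | 1.05 · Beta(5, 3) | EV = MV/s; < 0.5% of mass above 1, so rare MV > EV items occur, as in real tables |
| diameter | (6·EV/π)^(1/3) | rejected and redrawn below 3 mm |
| follow-up fraction | 2311/2715 ≈ 0.851 | Bernoulli per nodule |
| ΔT | 365 d | baseline to first recall |
| malignant fraction | 0.02 | nodules with true growth |
| true VDT | lognormal, median 150 d, log-sd 0.5 | log-sd is not derivable from the source; 0.5 keeps ~90% of true VDTs in 66–340 d, i.e. mostly within the probably-malignant band |
| measurement CV | 0.15 | median-1 multiplicative lognormal noise on re-measured volumes, log-sd √ln(1+CV²) |

Follow-up diameters reuse the nodule's own baseline shape ratio, so the
EV-based VDT of a noiseless nodule round-trips exactly. One follow-up
timepoint only. Identical (config, seed) yields byte-identical cohorts
(NumPy `default_rng` seeded through `SeedSequence([seed, round])`).

What the generator does **not** emulate: nodule morphology, segmentation
failure modes, attachment-driven diameter error, correlated per-screenee
measurement bias, multi-round trajectories, or cancer outcomes. Passing
calibration tests therefore shows the pipeline handles data with the right
marginal structure, not that the generator mimics any real cohort's joint
distribution.

Two numerical notes on the calibration tests. The 3 mm floor
left-truncates the volume distribution (post-rejection median ≈ 45 mm³),
so lognormal parameter recovery is assessed with the floor disabled
(`min_diameter_mm=0`): the floor is an eligibility rule, not part of the
volume model. The category-marginal check averages 20 fixed seeds at the
default cohort size, which runs in well under a minute.

## Degenerate inputs and tie-breaks

- Kappa is undefined for an empty table (error) and when expected agreement
  P_e = 1, i.e. both marginals concentrate in one category (error from
  `weighted_kappa`; reported as null in run reports, which can legitimately
  hit this on small or noise-free cohorts).
- Severity shift is undefined on a fully concordant table (explicit error).
- Dominance ties: volume, then diameter, then smallest nodule id — fully
  deterministic.
- Zero diameter/volume are accepted by the pure geometry helpers (0 → 0)
  but rejected by record validation and classification, which require
  positive measurements.

## Problem sizes

Fixture-table statistics are exact arithmetic on 3×3 integer tables. The
test suite's stochastic checks use 20 cohorts of 1583 screenees plus one
~10⁵-nodule cohort for parameter recovery; the full suite completes in a
few seconds on one CPU.

## Known limitations

- Printed percentages in the source tables are internally inconsistent in
  three places (40.1% vs 1115/2715 = 41.1%; 35.4% vs 472/1347 = 35.0%;
  16.9% vs 266/1583 = 16.8%); the integer counts are treated as
  authoritative everywhere.
- Whether the trial's indeterminate bands were closed intervals is unknown;
  all table-level statistics are unaffected because they start from the
  printed counts.
- The screenee-based VDT fixture's first column header is corrected from a
  printing error (">600" where "<400" is meant; the column sums and
  denominator only admit that reading).
- Sub-solid nodules are out of scope (excluded upstream of the data this
  models), as are image handling, miRNA risk profiling and any
  cancer-outcome analysis.
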