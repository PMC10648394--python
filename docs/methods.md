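# Methods

This note documents the models, algorithms and design choices behind the
package, and what the synthetic validation does and does not establish.

## Oxemic-risk score

The score maps arterial oxygen tension to an integer severity weight:

| PaO2 stratum (mmHg) | weight |
|---|---|
| ≤ 40 | 6 |
| 41–49 | 2 |
| 50–80 (normal) | 0 |
| 81–99 | 1 |
| 100–199 | 3 |
| ≥ 200 | 6 |

Hypoxemia is weighted more heavily than hyperoxemia of comparable distance
from normal, reflecting outcome studies linking low saturations to
mortality and high ones to developmental morbidity. The printed strata are
integers; to make the score total on real-valued PaO2 the gaps are closed
as (0, 40] | (40, 50) | [50, 80] | (80, 100) | [100, 200) | [200, ∞), which
preserves every integer's stratum and leaves no uncovered reals. The table
is overridable (YAML or `RiskWeightTable.from_breakpoints`) for weighting
sensitivity analyses; validation enforces structure (increasing bounds,
non-negative integer weights) but not the default values.

A record set's risk is the mean weight. Confidence limits use the normal
approximation mean ± z·s/√n (no method is canonical for this descriptive
score; a seeded percentile bootstrap with 2000 resamples is available as an
option and agrees with the normal interval at the sample sizes used here).
With n = 1 the sample s.d. is undefined; the interval collapses to the
mean and is flagged degenerate. Two subsets are read as "significantly
different" when their intervals do not overlap — a conservative
convention.

## SpO2 conventions

Averaged SpO2 values are binned to integer percent by round-half-up
(92.5 → 93); no binning convention is canonical, and half-up keeps bin 88
reachable from 87.5. A target range is an inclusive integer band; the six
candidates are ±2% around medians 90–95%, their union (88–97%) the
normoxemic envelope. PMA is gestational plus postnatal age in days,
rendered as weeks^days (278 days → `39^5`). A 120-s window mean is
provided for pairing a 30-s SpO2 stream with an arterial sample time
(mean of all stream values within ±120 s; an empty window yields NaN).

## Stratified sampling

750 records per integer envelope bin, uniformly **without replacement**
(drawing the same arterial sample twice would be meaningless), seeded.
Records are pre-sorted on all columns (subject first) so the draw is
independent of input row order and platform. Shortfall in a bin either
raises (default) or takes the whole bin with a logged warning.

## CHAID partitioner

Merge-only CHAID for a single ordinal predictor:

1. Categorise PMA at day (default) or week resolution.
2. Fold categories smaller than `min_leaf_n` (default 50) into their
   most-similar neighbour (largest pairwise p) *before* testing —
   chi-squared is unreliable on near-empty categories and every candidate
   child must meet the minimum anyway.
3. Repeatedly merge the adjacent pair with the largest pairwise p
   (leftmost on ties) while that p exceeds `alpha_merge` (0.05); stop when
   all adjacent pairs are significant or one group remains.
4. Adopt the r-way grouping only if the omnibus test p, multiplied by the
   Bonferroni factor C(c−1, r−1) (the number of contiguous r-groupings of
   c ordered categories) and capped at 1, is ≤ `alpha_split` (0.05). All
   merged groups then become children (nonbinary split); recursion depth
   defaults to 1, matching single-level multiway partitions.

Tests: in categorical mode (default) responses are the nominal score
classes {0, 1, 2, 3, 6} and pairwise/omnibus tests are Pearson χ² with
zero-margin classes dropped; in continuous mode they are one-way ANOVA
F-tests on the numeric weights. Degenerate tables (one class or one group)
score p = 1. Child intervals are normalised to tile the parent exactly
(`≤b | b+1…c | >c`), with boundaries at observed category values.

Known behaviour: the greedy merge inspects many intermediate states, and
with many day-resolution categories it can freeze at groupings with more
leaves than the generating truth (each surviving adjacency is locally
significant). The Bonferroni gate controls the family-wise rate of
splitting *at all* under the null (measured ≤ 0.02 at the calibration
settings in the acceptance suite), not the leaf count under signal; on
smooth risk gradients the trees are therefore finer than the printed
partitions of small real cohorts. Break-point *location* recovery is the
validated property.

## Synthetic cohort generator

The generator emulates the marginal structure of a tertiary-NICU blood-gas
repository; defaults:

* **Infants:** 888; gestational age from a two-piece log-normal hitting
  quartiles (32, 37, 39) weeks exactly, clipped to 22–46 weeks and rounded
  to days. Only quartiles are published, and the two-piece family matches
  all three while staying unimodal and skew-capable.
* **Samples per infant:** 1 + negative-binomial, (r, p) grid-fitted to
  quartiles (2, 5, 10); the default triple is matched exactly by the
  shifted geometric r = 1, p ≈ 0.136. With these counts a default cohort
  holds ≈ 6.8k records; analyses needing 750 per envelope bin scale
  `n_infants` (the worked example uses 6500 → ≈ 51k records).
* **Postnatal age:** per-record two-piece log-normal with quartiles
  (0.9, 2.0, 4.9) weeks, rounded to days, sorted within infant (serial
  sampling), capped at 26 weeks — a neonatal unit discharges or transfers
  long before half a year.
* **PaO2:** log-normal mixture of clinical states — hypoxemic event
  (w 0.22, median 43 mmHg, log-sd 0.18), stable (0.58, 64, 0.16),
  hyperoxemic overshoot (0.20, 120, 0.45) — reflecting that blood gases
  are drawn at exacerbations and weaning, not at random during stability.
  The defaults put ≥ 1% of draws in every scoring stratum.
* **SpO2:** the cubic-rational dissociation curve
  S = 100·(23400·(p³+150p)⁻¹+1)⁻¹ (monotone and invertible in closed
  form; its exact p50 is 26.8568 mmHg), with p50 shifts applied by abscissa
  rescaling p_eff = p·p50_ref/p50. The p50 follows a logistic blend from
  fetal 19 mmHg to adult 26.8 mmHg with midpoint 252 days (36 weeks) and
  scale 28 days, a smooth stand-in for the transfusion-modulated fetal
  hemoglobin decline. Oximeter noise is additive Gaussian, s.d. 2.0%,
  clamped to [50, 100] and recorded at 0.1% resolution.
* **Ground-truth break:** optionally, records with PMA above
  `pma_risk_shift_days` multiply the hyperoxemic state's weight by
  `shift_factor` (default 4, re-normalised) — a step change in mean risk
  of ≈ 0.5 used by the recovery experiments.

Everything is driven by one `numpy` Generator seed; identical
(config, seed) gives byte-identical CSV output.

**What the generator does not emulate:** intra-infant autocorrelation and
time-series dynamics (apnoea, FiO2 control), transfusion events, acid–base
and temperature shifts of the curve, calibration bias between SaO2 and
SpO2, and the real repository's heavy-tailed per-infant sample counts
(whose published total implies a mean near 30 samples per infant, which is
inconsistent with the published quartiles; the generator honours the
quartiles). Consequently, passing tests validate the *method* —
arithmetic, calibration, recovery of implanted structure — not any
clinical conclusion about real neonates. Real-data risk magnitudes are not
reproducible from synthetic cohorts and are never asserted.

## Validation design

* Scoring, binning, formatting: exact expected values, boundary semantics
  on a 0.1-mmHg grid.
* Sampling: exact design arithmetic (7500 / 3750) on a ≈ 51k-record
  cohort; inclusion-frequency uniformity 0.5 ± 0.05 over 2000 seeds.
* Pairwise test calibration: P(p ≤ 0.05) = 0.05 ± 0.02 under the null
  (2000 simulations, both modes).
* CHAID null: split rate ≤ 0.07 over 500 replicates of 20 independent
  categories, n = 2000.
* CHAID recovery: implanted break at PMA 252 days relocated to within
  ±7 days in ≥ 80% of 100 seeded n ≈ 5000 cohorts (observed: 100%).
* Merge step: membership in the fixed-point set of an exhaustive
  contiguous-grouping search on 100 random ≤ 6-category datasets.
* Bonferroni multiplier: brute-force cut-set enumeration for all c ≤ 12.
* CI coverage: 95% ± 2% over 1000 replicates of n = 10⁴ i.i.d. draws from
  a known weight distribution.
* Conservation identities (leaf n / proportion / pooled-mean, percentage
  sums, CI ordering) on every pipeline run, plus byte-identical reruns.

Simulation sizes were chosen to keep the default suite under half a
minute while leaving the Monte-Carlo tolerances comfortably resolvable.

## Numerical notes

* The dissociation curve's inverse uses Cardano's formula on the depressed
  cubic p³ + 150p = 23400·S/(100−S); round-trip error < 0.1 mmHg.
* χ² statistics are computed from count tables without continuity
  correction (the classic test; matches `scipy.stats.chi2_contingency`
  with `correction=False`).
* Merging operates on sufficient statistics (class counts, or
  (n, Σx, Σx²)), so a full merge pass over hundreds of categories costs
  milliseconds.
* Ties in merging are broken leftmost; all randomness flows through
  explicit seeds; no global RNG state is touched.
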