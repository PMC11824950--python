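# Methods

## Exposure model

All quantities are expressed in Defined Daily Doses (DDD), the WHO's
assumed average maintenance dose per day, so that different medications of
one therapeutic family (identified by ATC code) can be aggregated on a
common scale. One dispensation contributes `n_packs × ddd_per_pack` DDDs
(scenarios 2–3) or `ddd_per_pack` DDDs (scenario 1, emulating databases
where the pack count is missing and conventionally set to 1).

**Time axis.** Days are integers relative to conception: day 0 is the first
day of gestation and gestational week *w* spans days `[7w, 7w+6]`, so week
−4 is days −28…−22. Dispensations earlier than week −13 (day −91) are
discarded before any processing — even when their supply would reach the
exposure window — mirroring the data-extraction convention that a treatment
active at week −4 must have been dispensed from week −13 on. The
trajectory covers weeks −4 through `min(delivery week, 38)`; deliveries
past week 38 are clipped to that axis and DDDs redistributed past the
window (notably past birth) are dropped.

**Occasional dispensing (and all dispensing under scenarios 1–2).** Each
supply is consumed at 1 DDD/day. Supplies of the same substance are queued
one after the other: a supply starts at the later of its dispensation day
and the day after the previous same-substance supply is exhausted. A
fractional total places its residue on the final day (7.5 DDD → 7 days at
1, one day at 0.5), so integer-day resolution never loses mass.

**Regular dispensing (scenario 3).** Dispensations of one substance whose
consecutive gaps are all ≤ 45 days (one month of treatment plus 15 days of
flexibility) form a maximal refill chain; chains of length ≥ 2 are
*regular*, singletons *occasional*. Same-day same-substance dispensations
are merged (quantities summed) before gaps are computed, so gaps are
strictly positive. For a regular chain with mean dispensed quantity N̄ and
mean gap D̄, the rate **F = N̄/D̄** covers every day from the first
dispensation up to, and excluding, the last — mass exactly N̄(k−1) for a
k-dispensation chain — and from the last dispensation day the remaining
mass (exactly N̄) drains at `weaning_factor × F` per day (default ½,
modelling gradual weaning) until exhausted, with any fractional residue on
the final tail day. For equally spaced chains this reduces to a plateau
N/D of length (k−1)D followed by a tail N/(2D) lasting exactly 2D days.

Occasional and regular chains of one substance are redistributed
independently and summed; occasional supplies queue among themselves (in
day order) but not behind a regular chain's tail — the two dispensing
regimes are treated as separate mechanisms. Substances are summed day-wise
into the pregnancy's daily series, then cumulated into weekly values.

**Mass conservation.** Before truncation the daily series of a pregnancy
equals its dispensed DDD total to ~1e−12 (floating-point only); this is the
central invariant of the redistribution and is property-tested over random
cohorts.

**F scope.** F is computed per maximal chain. The phrase "between the
first and the last regular dispensation" presumes one contiguous window,
and the per-chain reading is the only one that remains well-defined when
regular episodes are separated by more-than-45-day gaps. The pooled
alternative (one F from all regular dispensations of a pregnancy ×
substance) is available as `ScenarioConfig(pool_regular=True)`; under a
pooled F a short chain's plateau could exceed its own dispensed mass, so
the plateau is additionally capped at the chain's remaining supply (a
no-op for per-chain F).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `regularity_window_days` | 45 | max renewal gap for a regular chain (days) |
| `lookback_week` | −13 | dispensations before this week are discarded |
| `window_start_week` | −4 | first week of the exposure window |
| `weaning_factor` | 0.5 | tail rate as a fraction of F |
| `exposure_epsilon` | 1e−9 | a pregnancy is exposed iff some weekly DDD exceeds this |
| `max_week` | 38 | trajectory axis cap (later deliveries clipped) |

"Exposed" means at least one weekly value above `exposure_epsilon` between
week −4 and `min(delivery, 38)`; an all-zero trajectory after truncation is
non-exposed even if the pregnancy had (pre-window) dispensations.

## Longitudinal clustering

Trajectories of different lengths are zero-padded onto the common week grid
(−4…38): exposure attributable to a pregnancy is zero after it ends, and
padding keeps Euclidean distances well-defined. This is an implementation
choice — available-case distances or imputation are alternatives — and its
main consequence is that early deliveries are pulled toward low-exposure
clusters, which is consistent with reading the trajectory as pregnancy
exposure. Trajectories are clustered raw (unstandardized) so that clusters
separate by exposure magnitude, matching the DDD scale of the trajectories
themselves.

k-means uses Lloyd's algorithm with Euclidean distance: `n_starts` (default
20) random initializations of k distinct rows, at most 300 iterations,
convergence when assignments stabilize, ties in nearest-centroid assignment
broken toward the lower cluster index, and a cluster emptied during
iteration re-seeded with the point farthest from its current centroid. The
run with the lowest within-cluster inertia wins; the fit is deterministic
given the seed, and the per-iteration inertia trace is retained (it is
non-increasing, which is asserted in tests). Final clusters are relabelled
A…D by ascending centroid mean, so A is always the least-exposed group.
scikit-learn's `KMeans` serves as an independent cross-check of the
attained inertia in the test suite, never as the implementation.

Partition quality is the Calinski–Harabasz criterion
`(B/(k−1)) / (W/(n−k))`, with B the size-weighted between-cluster sum of
squared centroid deviations and W the within-cluster sum of squares; a
partition of duplicated points (W = 0) is reported as degenerate
(infinite). The implementation is checked against a brute-force double
loop and against `sklearn.metrics.calinski_harabasz_score`.

## Scenario comparison

Step 1 pools all weekly values of all exposed pregnancies of a scenario:
count of exposed pregnancies, sum of DDDs, and the pooled weekly mean,
sample sd, 90th/95th percentiles (empirical quantiles, linear interpolation
between order statistics — fixed so outputs are reproducible) and maximum.
Step 2 compares one pregnancy's two trajectories week by week with an
absolute tolerance of 1e−9 ("strictly identical" under floating-point
redistribution); changed trajectories whose DDD totals agree to the same
tolerance are *compensated*. Step 3 cross-tabulates two partitions over
{A, B, C, D, Non-exposed}: the grand total always equals the cohort
universe and the margins equal the per-scenario category counts, and the
table carries counts of status changes, cluster switches and switches of
≥ 2 levels (letter order A<B<C<D by centroid mean). Per-cluster summaries
reduce each pregnancy to its average weekly DDD (trajectory sum / length)
before computing cluster statistics — deliberately distinct from the pooled
weekly mean of Step 1, which weights pregnancies by trajectory length.

## Synthetic cohorts

The generator emulates the structure the method assumes, not any real
database. Per cohort: delivery week ~ round(N(39, 2)) clipped to 25–43;
a configurable fraction of pregnancies (default 0.8) is exposed. Each
exposed pregnancy draws one of four exposure strata with weights
0.767/0.129/0.084/0.020 and target mean weekly DDD levels 0.55/2.6/7/16 —
the skewed low-to-very-high mix typical of psychotropic exposure — jittered
log-normally (σ = 0.15) per pregnancy. The level is realized through 1–4
substance episodes (distinct ATC codes from a 17-entry pool spanning pack
contents of 0.5–50 DDD): regular refill chains start within a week of the
window start and refill every ~N(30, 5) days (truncated to 7–44, a monthly
habit kept inside the regularity window) until delivery, while occasional
episodes are one or two small supplies placed uniformly in the pregnancy,
with any renewal forced beyond 45 days so intent matches classification.
Chain totals are inflated by the expected out-of-window fraction (weaning
tail past delivery, pre-window days) so the planted level refers to
in-window exposure. Pack counts are 1/2/3 with probabilities
0.68/0.22/0.10, independent of the target, so roughly a third of
dispensations involve more than one pack. Because an occasional supply is
consumed at 1 DDD/day it cannot express a sustained high level; a pregnancy
whose target exceeds a small one-off supply (45 DDD) is therefore given at
least one refill chain — unless regular dispensing is disabled entirely
(`regular_fraction=0`), the configuration used to exercise the
scenario-3 ≡ scenario-2 degeneracy.

Planted stratum labels are emitted beside the records so clustering
recovery is measurable without circularity; they are never an input to the
pipeline. What passing tests show is that the pipeline recovers a planted
level structure under these conditions (adjusted Rand index ≥ 0.9 at 5,000
pregnancies); real dispensation data add features the generator does not
model — treatment switches and interruptions, dose titration, seasonality,
co-prescription correlations — so recovery there is an empirical question,
not a consequence of these tests.

## Problem sizes and numerics

The verification experiments run at 1,000 pregnancies (mass conservation,
scenario ordering), 500 (each degeneracy), 5,000 (cluster recovery), 200
(queueing oracle) and 100 random cases (concordance bookkeeping); each
completes in seconds on one core and the sizes are comfortably past where
the measured quantities stabilize. Redistribution drops only residues
below 1e−12 of a supply; weekly sums equal surviving daily sums exactly.
Degenerate inputs are defined: an empty dispensation list yields an empty
exposure, a pregnancy with no dispensations a zero trajectory, and an empty
trajectory collection a 0-row matrix.

## Known limitations

* The model redistributes *supply*, not ingestion: adherence, stockpiling
  and discards are invisible to dispensation data.
* The weaning tail is a single F/2 step; real tapering schemes vary.
* A substance is "renewed" only by the identical ATC string; switches
  within a class break a chain.
* DDD content per pack is an input column; no ATC/DDD dictionary lookup is
  performed.
* Trajectories are capped at week 38; exposure in later post-term weeks is
  not represented.
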