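# Methods

Statistical and algorithmic details of the `pairguard` pipeline: what each
stage computes, the parameter defaults and their rationale, the mixed-model
machinery, and the scope and known limitations of the synthetic validation
data.

All timestamps are UTC. "Local day" boundaries use a fixed UTC−8 offset
(`proximity.LOCAL_UTC_OFFSET_H`), appropriate for an Alaskan study area;
"day 0" is the local day of clutch initiation, negative days precede it.
The expected sampling cadence is one GPS fix per bird per 10 minutes
(144 slots per local day).

## 1. Track filtering (`pairguard.filtering`)

Three plausibility rules, applied in order, each with a strict `>`
comparison so boundary values are kept:

| Rule | Default | Removes a fix when |
|---|---|---|
| far | 500 km | distance from the bird's capture location > `max_dist_from_capture` |
| speed | 105 km/h | speed from the previous *retained* fix > `max_speed` |
| single outlier | 2.5 km jump, 100 m neighbors | the fix is > `outlier_jump` from both temporal neighbors while those neighbors are within `outlier_neighbor_window` of each other |

The defaults are conventional shorebird-telemetry screening values: far
catches corrupted coordinates, speed catches unreachable displacements
(105 km/h exceeds sustained phalarope flight speed), and the single-outlier
rule catches isolated position spikes flanked by consistent fixes. Fixes
are also clipped to each bird's deployment interval (closed on both ends).
`filter_dataset` returns the kept fixes plus a `FilterReport` whose counts
satisfy the conservation identity
`n_input − removed_far − removed_speed − removed_single_outlier = n_kept`;
the report is additive across datasets. Filtering is idempotent apart from
the speed rule's dependence on the retained sequence, which the tests check
directly.

## 2. Fix pairing and the "together" classifier (`pairguard.proximity`)

Male and female fixes are matched one-to-one by a greedy pass over candidate
matches sorted by ascending time gap, capped at `max_pairing_gap = 10` min.
The slot time of a matched pair is the midpoint of the two fix times.
Coordinates are projected to a local azimuthal-equidistant plane before
distances are taken; at study-area scale (< a few km) the projection error
is negligible.

A matched pair is labeled together by three rules:

1. **Dynamic threshold.** Distance < `base_threshold + gap_allowance_rate ×
   gap`, i.e. 30 m + 12 m/min × pairing gap. The allowance grows with the
   gap because two birds walking together at ordinary foraging speed drift
   apart in expectation by roughly this much per minute of asynchrony
   between their fixes.
2. **Bout confirmation.** A run of rule-1 slots counts as a together bout
   only if at least one slot in the run has distance < the fixed 30 m. This
   removes runs that only ever pass because of the gap allowance.
3. **Final-slot relabel.** The last slot of a confirmed bout is relabeled
   apart if its distance is strictly > 30 m: the pair has in fact already
   begun separating by that fix.

The vectorised implementation is tested against a literal, slot-by-slot
reference implementation (`classify_together_reference`) on thousands of
random tracks, including a property-based (Hypothesis) test.

`daily_proportions` aggregates labels to pair × local-day proportions;
`window_mean` averages the per-pair means over day windows. The analysis
windows are pre-laying (−5…−1), laying (0…3), fertile (0…2) and incubation
(4…10) days relative to clutch initiation.

## 3. Separation events (`pairguard.separation`)

A separation event is a together→apart transition in a pair's slot sequence;
the event count equals the transition count by construction (property-based
test). For each event the displacement of each bird between the last
together slot and the first apart slot is computed; the **mover** is the
bird with the larger displacement (a tie yields `mover = "tie"` and an
undefined mover displacement). `partner_stationary` flags events where the
non-mover moved less than half the mover's displacement, the regime in
which attribution is most reliable. `separation_day_stats` and
`separation_distance_table` summarize counts and displacement distributions
by day and by mover sex.

Attribution is displacement-based, not trajectory-based, so it degrades when
the separation begins while the pair is jointly traveling: both birds then
show large displacements and the rule can select the partner. On synthetic
data, attribution accuracy for flights ≥ 3× the GPS noise SD is ≈ 0.93–0.95
overall and ≈ 0.98 conditional on a stationary partner; users should prefer
the `partner_stationary` subset when individual-level attribution matters.

## 4. Nest attendance (`pairguard.nest`)

A fix is at the nest when it is within `NEST_RADIUS_M = 15` m (inclusive)
of the nest coordinate — a radius that absorbs GPS noise (≈ 5 m SD per
coordinate) while staying below typical inter-nest distances. Per slot the
classifier reports, for each sex, at-nest status split into *with mate*
(both at nest and the slot is labeled together) and *alone*, so that
`at_nest = with_mate + alone` holds exactly. `first_nest_visit_day` gives
each bird's first at-nest local day relative to initiation, with a flag for
visits before day 0.

## 5. Random-pair null (`pairguard.nullpairs`)

To test whether pair cohesion exceeds incidental co-occurrence, the together
classifier is run on non-breeding male–female dyads. For each focal nest-day
in (−5…10), up to `n = 50` eligible dyads are sampled without replacement
(deterministic under a seed; shortfalls are recorded). A dyad is eligible on
a date when (1) both birds have fixes covering ≥ 50 % of that local day,
(2) the dyad was together in at least one slot somewhere in the record
(ever-together, ensuring the two birds use overlapping areas), and (3) the
dyad is not a breeding pair. Breeding pairs at shared sites produce a
random-dyad baseline of roughly 0.10 together under study-like conditions;
`null_comparison` reports window means by pair type and a breeding-vs-random
contrast with a p-value.

## 6. Clutch-initiation phenology (`pairguard.phenology`)

`estimate_clutch_initiation` combines evidence channels in priority order:

1. manual override (field-determined date),
2. nest discovered during laying: back-date by one day per egg already laid
   (one egg laid per day),
3. observed hatch date: initiation = hatch − (clutch size − 1) − incubation,
   with incubation 17 days for artificially incubated clutches and 19 days
   for naturally incubated ones,
4. egg flotation: back-date the discovery date by the flotation-estimated
   embryo age (rounded to whole days) plus one day per additional egg
   present at discovery,
5. (fallback) onset of male nest visits from telemetry.

Clutch size is capped at 6; when two channels diverge by three days or more
a warning is emitted and the higher-priority channel wins. The return value
is `(date, method)` so downstream tables can stratify by estimation method.
`standardize_init_date` centers dates within year; `assign_clutch_order`
orders a female's clutches to identify re-nesting and polyandrous sequences
(`split_renest_data`).

## 7. Mixed models (`pairguard.glmm`)

`fit_glmm` fits binomial, beta-binomial and Gaussian responses with fixed
effects and per-group random intercepts (optionally random slopes, Cholesky
parameterized). The marginal likelihood integrates the random effects with
a **Laplace approximation**: per-group posterior modes by damped Newton
iteration, then a second-order expansion around the modes. The outer
optimization is L-BFGS-B (maxiter 1000, ftol 1e-12, gtol 1e-8) with a
numeric Hessian for Wald standard errors. The beta-binomial response uses a
log-parameterized dispersion φ.

Numerical safeguards (all exercised by the tests):

- The beta-binomial log-likelihood is **not globally concave** in the linear
  predictor, so the inner Newton step can point downhill or the per-group
  observed Hessian can be indefinite. The inner loop therefore backtracks
  (halving, 25 steps), falls back to a preconditioned gradient step whenever
  the Newton direction is not an ascent direction, and retries from a cold
  start if a warm start breaks down. The Laplace log-determinant floors the
  per-group curvature eigenvalues at 1e-10 instead of failing. Without
  these, a flat penalty plateau can make the outer optimizer "converge" at
  its starting point with zero gradient.
- A fallback ladder refits with a simpler covariance (full → diagonal →
  intercept-only) when a fit does not converge.

Correctness oracles: exact agreement with OLS/GLM when no random effect is
present; the two-cell binomial model reproduces 2×2 contingency log-odds
analytically; Gaussian random-intercept-and-slope fits match
`statsmodels.MixedLM` (ML) to ≤ 1e-4 in coefficients; Laplace marginal
log-likelihoods match an adaptive Gauss–Hermite quadrature oracle
(`marginal_loglik_quadrature`, 21 nodes) to ~1e-4 **relative** for binomial
and beta-binomial random-intercept models. The quadrature agreement is
assessed on a relative scale because the Laplace approximation's own error
is O(1/cluster size) — demanding near-machine absolute agreement on a
log-likelihood of order −450 would test the wrong thing.

`select_quadratic` adds a quadratic day term and drops it when its Wald
p-value exceeds 0.05; under a truly linear data-generating process the
type-I error of this drop rule is 5 % ± 2 (500-simulation check).
`diurnal_terms` builds a cosinor (sin/cos of local time of day);
`fit_diurnal_model`/`diurnal_amplitude` recover a planted 10-point
day-night effect within ±3 points on synthetic data.

## 8. Synthetic data (`pairguard.synthetic`)

`simulate_pair_tracks(SimConfig)` renders a full season of 10-minute fixes
for `n_pairs` pairs plus a `TruthLog` (per-slot together and at-nest truth,
every scripted separation flight with mover and flight distance, every
planted corrupted fix). Defaults reproduce study-like conditions:

- day profile of together probability 0.90 (pre-laying) → 0.84 (day 0) →
  0.28 (day 3) → 0.10 (incubation); separation rates 1.9/4.6/3.0 per day by
  phase; female-mover probability 0.45 pre-laying / 0.52 after;
- flight distances log-normal (median 155 m, log-SD 0.5, capped 2 km);
  flights > 200 m are step-rendered at 140 m/slot rather than teleported;
- GPS noise 5 m SD per coordinate; per-pair tag-schedule lag ~N(2.6, 1.2)
  min (clipped), giving a pooled median pairing gap of ≈ 2.6 min by
  construction;
- three shared foraging sites with site attraction 0.7 and lone-bird speed
  2.4 m/min, calibrated so random dyads co-occur ≈ 0.10 of the time;
- optional planted corruption (`outlier_rates`) and a plantable diurnal
  amplitude for cosinor validation.

Truth labels are generated under the same operational together definition
the classifier uses, so slot-level recovery is a test of the measurement
chain (noise, pairing, bout logic), not of a definition mismatch.

**Known limitations / residual biases.** (1) Measured separation events
exceed scripted ones by ≈ 10 %: noise near the threshold and genuine site
co-occurrence create extra short transitions. (2) Mover attribution errors
concentrate in separations that begin during joint pair travel (see §3);
this is shared measurement physics, not a generator artifact, and was
deliberately not calibrated away. (3) The measured mover displacement
undershoots the scripted flight distance when a flight is step-rendered
across a slot boundary. (4) The movement model is a site-attracted
correlated random walk; it does not model altitude, habitat structure or
weather-driven movement.

## 9. Reproducibility

Every stochastic component takes an explicit seed; `simulate_pair_tracks`
is bit-identical under a fixed `SimConfig`. `pairguard run` and
`scripts/acceptance.py` derive all sub-seeds from a single user seed (kept
below 2³¹). The acceptance report
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
re-computes the classifier oracle, a full synthetic-season recovery against
the truth log, the null comparison and the model diagnostics in ≈ 30 s.
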