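# Methods

## Setting and definitions

The package analyses a longitudinal stream of insurance claims (one row per
in- or outpatient claim: patient, sex, birth date, claim type, service
date, ICD-10 diagnosis codes) to decide how long a look-back period (LP)
is needed before an index year so that patients classified as incident are
truly new cases, not prevalent patients whose history fell outside the
window.

Two rules are deliberately different and both configurable:

* **Case rule** (defines the index-year prevalent pool): at least 1
  inpatient disease claim or at least 3 outpatient disease claims inside
  the window. Inpatient diagnoses are treated as more reliable than a
  single outpatient contact.
* **Exclusion rule** (applies inside the LP): *any* disease-coded claim,
  either type, any count, reclassifies the patient as prevalent.

"Disease" is a prefix predicate on ICD-10 codes; the default is diabetes
mellitus, E10–E14, any subcode.

LP windows are calendar-aligned: a k-year LP for index year Y is
Jan 1 (Y−k) … Dec 31 (Y−1); fractional LPs step back whole 3-month
calendar blocks. The default grid is quarter-year steps through the first
year, then whole years to 4 — the region where the incident count moves
fastest gets the finest resolution. The longest grid LP is the reference.

## Concordance (CEI) engine

Each LP's incident set is compared with the reference LP's on the
prevalent pool as a 2×2 table (a = incident under both, b = LP only,
c = reference only, d = neither). Longer LPs can only remove patients, so
the sets are nested, c = 0, and PPV = a/(a+b) = n_ref/n_LP; both
identities are asserted in tests. Cohen's κ uses the standard
p_o = (a+d)/n, p_e = [(a+b)(a+c) + (c+d)(b+d)]/n². At the reference LP, κ
is reported as not applicable rather than 1.0 (agreement with itself
carries no information); the recommender treats that row as passing the κ
cut-off. All proportions are computed exactly and only rounded (half-up, 3
decimals) at reporting.

Default acceptability cut-offs: κ ≥ 0.9, PPV ≥ 0.90, overestimation
≤ 0.10. Published conventions vary (κ bands of 0.8 vs 0.9, PPV 80% vs
90%, overestimation 10% vs 20%), so all three are plain configuration.

## Retrograde survival engine

Per prevalent patient: a = date of the **last** disease record in the
index year (the convention follows the method's original formulation; a
first-record convention would shorten all times by the within-year span
but not change the machinery), b = most recent disease record in the LP
window, c = first day of the window. Event time a−b (b exists), censoring
time a−c (no prior record). Times are whole days and strictly positive.

S(t) is the Kaplan–Meier product-limit estimate; the fitting is delegated
to lifelines and re-expressed as a daily table (n_t at risk at the start
of day t, d_t events during day t, S right-continuous). Tests cross-check
it against a hand-rolled product-limit computation and against 1 − ECDF on
censoring-free data.

The actuarial hazard is h_t = d_t / n_t with Δt = 1 day. Two optional
controls exist because the raw daily hazard of a small cohort is noisy:

* `window` (days): h_t = (events over [t, t+w)) / n_t on a sliding
  window. Default 1 (raw). For simulated cohorts of ~2×10⁴ patients we
  use w = 30: with daily events in the tail in the single digits, a
  month-scale window is the smallest that keeps sampling noise from
  producing arbitrary first-crossing days; at the ~10⁵ scale of a real
  claims database the raw hazard is already smooth.
* `min_day`: the first-crossing scan for t_f (first day with
  h_t ≤ 0.0005) starts there. Default 0. On small cohorts the earliest
  days can contain no events at all (h = 0 spuriously); scanning from the
  hazard's peak day — or from any day clearly past the initial rise —
  avoids declaring convergence before the hazard has even risen. The
  threshold 0.0005 itself is the published operating point: stricter
  thresholds (e.g. 10⁻⁵ in earlier literature) are known to inflate the
  LP to a decade or more.

The frequency rule rounds S(t) to 2 decimals (the scale at which reported
stable values like 0.10/0.11 are distinguishable) and counts the days
spent at each value. Scanning values from high to low, the **stable S** is
the first value whose dwell time is at least `jump_factor` (default 2.0)
times the dwell time of the next-higher value *and* is the overall
maximum; t_f_freq is the first day S reaches it. The two conditions
formalize "the frequency is high and increases significantly": the jump
alone can fire on a mid-curve shoulder, the peak alone is reached by any
terminal plateau, including a slowly drifting one.

The combined recommendation is the smallest grid LP that passes all CEI
cut-offs and covers both defined convergence days, converting years to
days at 365.25. If neither t_f is defined the CEIs alone decide; if no
grid LP qualifies the result carries diagnostics instead of a value.

## Synthetic claims generator

The generator emulates the statistical structure the method relies on —
recurrent disease-coded contacts after a latent onset — with ground truth
for every patient:

* Onset mixture: with probability `prevalent_fraction` (default 0.5) the
  onset predates the horizon (uniform over the 10 years before it),
  otherwise it is uniform inside the 5-year horizon (2016–2020). Contacts
  start *at* onset — no pre-onset disease claims — which is the
  identifying assumption that makes the LP method work at all.
* Contact process: a renewal process from onset to the horizon end.
  Regular patients (90% by default) draw gamma gaps, shape 2, mean 40
  days ≈ 9 disease-coded visits/year, matching the outpatient
  visits-per-capita magnitude of large urban claims data for diabetes.
  Irregular patients draw log-normal gaps, median 200 days, σ = 1 — a
  heavy tail that can silently span several years. Each contact is
  inpatient with probability 0.04 (the inpatient:outpatient ratio seen in
  such data).
* Background claims (non-disease codes, Poisson 2/patient-year) exercise
  the code predicate; record-level missing sex (2×10⁻⁵) and missing
  diagnosis (4.9%) exercise the cleaning stage at the rates such databases
  report.

All randomness flows from one integer seed; identical configs are
byte-identical.

What the generator does **not** model: mortality and emigration (loss to
follow-up), demographic structure in contact behaviour, multiple
simultaneous diagnoses per claim, secular trends in utilization, or
type 1 / type 2 differentiation. Passing tests therefore demonstrate the
pipeline's correctness and the method's internal behaviour, not claims
about any real population's optimal LP.

Two deliberate consequences of the "a = last index-year record"
convention show up in simulation and are worth understanding:

* For a regular visitor the retrograde time a−b spans the whole gap
  between their last pre-index and last index-year contacts, so event
  times concentrate near one year plus a gap, not near the gap itself.
  The survival curve of the *gap distribution* is therefore probed by a
  dedicated fixture (`simulate_gap_probe`) in which each patient's last
  index-year record falls on Jan 1 of the index year and exactly one
  prior record sits one gap-draw earlier; the standard pipeline then
  estimates the gap survival function directly (KS distance ~0.006 at
  n = 2×10⁴ against the closed-form gamma).
* Adding the 10% irregular component moves the hazard-convergence day
  substantially later (≈560 → ≈850 days at n = 2×10⁴): irregular medical
  contact is exactly what lengthens the required LP.

## Problem sizes

Desk-scale reproductions (the concordance identities on printed counts)
are instantaneous. Simulation-based checks use 20,000 patients (~9×10⁵
claims, a few seconds to generate and fit), the size at which the KS
tolerance of 0.02 and the directional hazard comparison are comfortably
stable across seeds; unit tests use 200–2,000 patients.

## Numerical conventions

* Dates are day-resolution; all durations are integer days.
* Half-up rounding (not banker's) for reported proportions, matching how
  published tables are printed.
* Cleaning removes missing-sex records first, then missing-diagnosis; a
  record missing both is counted once, under sex. Cleaning is idempotent.
* κ is NaN when expected agreement is 1 (degenerate marginals); PPV is
  NaN when no positives exist; utilization ratios are NaN (never 0) for
  empty cells.
* Unknown diagnosis codes pass through harmonization unchanged and are
  tallied; unparseable input rows are collected with line numbers, never
  silently dropped.

## Known limitations

* The exclusion rule follows the "any record" formulation literally; a
  variant requiring the full case rule inside the LP would classify a few
  single-contact patients differently.
* The recommender's year↔day conversion (365.25) can matter only when a
  convergence day lands within a day or two of a grid boundary.
* The stable-S rule needs the curve to actually dwell at a terminal
  plateau; on heavily censored small cohorts it returns no value (with
  diagnostics) rather than guessing.
* Age stratification assumes birth dates are constant per patient and
  computes age on Dec 31 of the index year.
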