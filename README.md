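# lookback

Optimal look-back period selection for incident-case ascertainment in
longitudinal medical-claims data.

## The problem

Administrative claims databases have a finite history. When you count the
*incident* (newly diagnosed) cases of a chronic disease such as diabetes in
an index year, every prevalent patient whose earlier records fall outside
the database looks like a new case. The standard fix is a **look-back
period (LP)** — a washout window before the index year — and to reclassify
anyone with *any* disease-coded claim inside it as prevalent. Too short an
LP overestimates incidence; too long an LP wastes data and restricts the
usable study window. This package implements two complementary ways to
choose the LP, for epidemiologists working with claims streams:

1. **Consistency examination indexes (CEIs).** Using the longest feasible
   LP as the reference classification of the index-year prevalent pool,
   each shorter LP yields a 2×2 agreement table. Because longer LPs only
   remove incident cases, the incident sets are nested and the table's
   "reference-only" cell is empty. Per LP we report

   - Cohen's κ = (p_o − p_e) / (1 − p_e),
   - PPV = a / (a + b) = n_ref / n_LP (under nesting),
   - overestimation = (n_LP − n_ref) / n_ref.

2. **Retrograde survival.** For each prevalent patient let *a* be the date
   of their last disease record in the index year, *b* the date of their
   most recent disease record in the LP window (if any) and *c* the first
   day of the window. Running time backwards from *a*, the "event" is
   finding a prior record: observed at *a − b* days, censored at *a − c*.
   S(t) = P(T > t) is estimated by Kaplan–Meier; the daily actuarial
   hazard h_t = d_t / n_t measures how quickly prior records are still
   being found at depth t. The LP has converged at the first day t_f with
   h_t ≤ 0.0005 (configurable), and, as a second reading, at the first day
   S(t) reaches the *stable* value — the rounded S value whose dwell time
   (days spent at that value) at least doubles and peaks.

The recommended LP is the smallest grid value that passes all CEI
thresholds (κ ≥ 0.9, PPV ≥ 0.90, overestimation ≤ 0.10 by default) and
covers both convergence days.

Because real claims databases are rarely shareable, the package ships a
synthetic claims generator with ground truth: patients acquire the disease
at a latent onset date and afterwards make recurrent disease-coded contacts
(a renewal process — gamma gaps for regular visitors, heavy-tailed
log-normal gaps for an irregular minority), so every pipeline stage is
testable end to end.

## Worked example

```python
from lookback import LookbackModel, SimulationConfig, simulate_claims, clean_claims

claims, truth = simulate_claims(SimulationConfig(n_patients=2000, seed=7))
claims, report = clean_claims(claims)   # drops missing-sex / missing-diagnosis records
res = LookbackModel(claims, index_year=2020).fit(hazard_window=30, min_day=365)
print(res.summary())
```

```
Look-back period analysis
================================================================
Index year:            2020
LP grid (years):       0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0   (reference: 4.0)
Prevalent pool:        1797
Retrograde obs:        1797 (1662 events, 135 censored)

Consistency examination indexes (vs reference LP)
----------------------------------------------------------------
 LP (y)  incident     PPV   kappa  overest
   0.25       237   0.570   0.697    0.756
    0.5       157   0.860   0.918    0.163
   0.75       149   0.906   0.946    0.104
    1.0       147   0.918   0.954    0.089
    2.0       138   0.978   0.988    0.022
    3.0       135   1.000   1.000    0.000
    4.0       135   1.000     N/A    0.000

Retrograde survival
----------------------------------------------------------------
Hazard threshold:      0.0005
t_f (hazard rule):     593 days
t_f (frequency rule):  545 days (stable S = 0.08)

Recommended LP:        2.0 years
```

Reading it: of 1797 patients meeting the diabetes case rule in 2020 (≥1
inpatient or ≥3 outpatient disease claims), a quarter-year washout keeps
237 as "incident", of whom only 57% are incident under the 4-year
reference — a 76% overestimate. By a 2-year LP the agreement is excellent
(κ = 0.988) and the overestimate is 2%. The retrograde hazard converges
(drops below 5×10⁻⁴) 593 days back, and S(t) settles at its stable value
0.08 from day 545 — both inside 2 years, so 2 years is recommended. The
`hazard_window=30` / `min_day=365` arguments smooth the daily hazard and
skip its empty early region, which matter at this cohort size (see
`docs/methods.md`).

`res.cohort` holds the per-LP incident rosters, `res.curve` / `res.hazard`
the daily survival and hazard tables, and `res.plot_survival()` /
`res.plot_hazard()` draw them. The same analysis runs from the shell:

```sh
lookback simulate --n-patients 2000 --seed 7 --claims-out claims.csv --truth-out truth.csv
lookback survival claims.csv --out-dir out/
lookback run config.yaml        # full pipeline from a YAML config
```

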