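# Methods

## Model overview

Both scenarios are expected-utility grid searches driven by Monte Carlo
resampling. A scenario defines a finite decision grid (probing depths
0.5–2.5 m; CPR durations 0–30 min), draws the random accident variables
from their distributions, computes each run's survival probability
deterministically from the draws, and averages over runs per grid point.
The reported optimum is the grid argmax of mean survival (probe line) or of
the expected number of survivors (CPR triage), with ties broken toward the
smaller grid value — shallower probing and shorter CPR, the choices that
cost the least when indifferent.

Random burial depths are resampled uniformly from an *empirical*
distribution (each recorded value with probability 1/n) rather than from a
fitted parametric law: registry depth data are plentiful enough that the
empirical law is the most faithful description, and resampling keeps heavy
tails and discretization exactly as recorded.

### Probe line

The debris area `A` is unrolled into a single strip of width `w = 1.5 m`
(the lateral coverage of one slalom-probing pass) and length `L = A/w`.
Per run: position `x ~ U(0, L)`, depth `d` from the empirical distribution.
A subject with `d` greater than the probing depth is missed and scores
survival 0; equality counts as found (the probe tip just reaches the body —
the physically sensible limit, which the two strict rules "deeper → missed"
/ "shallower → found" leave open). For found subjects,

    t_search = x / (v_search(p) * n_rescuers),   t_dig = d / v_dig,

and survival is `S(t_search + t_dig)`. Lateral probe misses and
line-reformation overhead are not modelled; rescuers multiply the advance
speed exactly.

`v_search(p)` is a power law `13 * (0.5/p)^β m/min` per rescuer with
`β = ln(13/1.5)/ln(2.5/0.5) ≈ 1.342`, i.e. the unique power law through the
two published endpoints of the slalom technique (13 m/min at 0.5 m probing
depth, 1.5 m/min at 2.5 m). The published speed–depth relation is a figure,
not a table; the power law is the package's parsimonious stand-in, and
`SpeedLaw` accepts other endpoint pairs (or a user-supplied curve via the
same interface) where a digitized table exists. Outside 0.5–2.5 m the speed
clamps to the endpoint value and logs a warning.

### CPR triage

Patient 1's ROSC probability after `t` minutes of CPR is the saturating
exponential `p1 = a(1 − exp(−0.07 t^1.3))`; it has no random inputs and is
evaluated deterministically. The ceiling `a` — the resuscitable fraction —
is tabulated against patient 1's burial time (12 → 0.62, 20 → 0.25,
35 → 0). Lookups beyond the last entry return its value (longer burials
cannot do better than zero); untabulated intermediate times raise rather
than silently interpolate, because the table is too sparse for
interpolation to be defensible — pass `a` explicitly instead. Patient 1's
arrest clock is taken to start at burial (the witnessed burial time is an
upper estimate of the arrest time); no additional excavation lag is added.

Patient 2's burial time per run is
`t_burial,1 + t_cpr + t_search + d / v_dig` with `t_search ~ max(0, N(2,1))`
min and `d` resampled as above, independent of `t_search`. Expected
survivors `p1 + mean_p2`, both-survive `p1 * mean_p2` and at-least-one
`1 − (1−p1)(1−mean_p2)` use the independence of the two patients' outcomes
and are computed from `mean_p2` exactly as identities of the table.

## The survival curve (the one non-printed ingredient)

Survival vs burial time for a completely buried subject is published only
graphically. The package ships a piecewise-linear digitization, version
`v1` (`avrescue/defaults/survival_curve_v1.yaml`): a plateau at 0.92 over
the first 10 min, decline through 0.76 at 20 min and 0.45 at 30 min to 0.33
at 35 min (asphyxia phase), then a shallow tail 0.27 → 0.24 → 0.19 → 0.07
at 45/60/90/130 min. Interpolation between knots is linear — it cannot
overshoot the knots, so the non-increasing invariant holds exactly, which
smooth splines do not guarantee. Beyond the last knot the last value holds.

Every Results object and run manifest records the curve version. Users with
their own digitization load it with `SurvivalCurve.from_yaml` and pass it to
the models. Quantities downstream of the curve (the probe-line optimum, the
CPR optimum, patient 2's averages) inherit its digitization error; the
package treats them as curve-conditional, and the test suite asserts only
banded or structural claims about them (see Limitations).

## Randomness and reproducibility

Generators are numpy `default_rng` seeded through `SeedSequence`. Within
one model's `.fit()`, a single draw set (position fraction / search time,
burial depth) is shared by every grid point — common random numbers. This
makes the within-grid invariants hold sample-wise and exactly: the miss
fraction is non-increasing in probing depth, and patient 2's mean survival
is non-increasing in CPR duration, because each sample's outcome is
monotone in the grid variable. It also removes independent resampling noise
from grid-to-grid comparisons, which is the variance-optimal way to
estimate an argmax on a grid. Sweeps (per area, per burial time) give each
case its own child stream with entropy `(root seed, case index)`, so any
single case is reproducible in isolation and results do not depend on
sweep order. Fixed seeds give bit-identical tables.

Each fit records a convergence diagnostic: the largest first-half vs
second-half deviation of the per-grid-point mean, in pooled standard
errors. The default 10,000 runs per grid point leave the grid means with
standard errors around 0.002–0.005, comfortably below the effect sizes the
optimizers discriminate, and the run-doubling tests confirm stability.

## Synthetic data

`generate_records` draws burial depths and deposit areas from log-normal
laws — both quantities are positive and strongly right-skewed, and the
log-normal is the simplest two-parameter family with that shape. It is a
configurable emulator, not a claim about the true laws. Defaults: depth
median 1.0 m with log-sd 0.6, area median 7200 m² with log-sd 1.2; only the
area median is anchored to a published value, the others are plausible
placeholders. Missingness is applied per field (defaults 4% of depths, 65%
of areas, mirroring registry proportions); when both fields of a record
would be masked the depth is kept, so every record stays usable.

`synthetic_s1_records` is the registry-snapshot stand-in used throughout
the tests: log-normal shapes rank-calibrated — the sample is rescaled so
one order statistic equals a published value, which preserves shape while
making the published fact exact. Depths: n = 1490, 447th smallest pinned to
0.50 m, so exactly 1043/1490 ≈ 70% exceed 0.5 m. Areas: n = 541, median
pinned to 7200 m². 477 records carry both fields, 1013 depth-only, 64
area-only, plus one row with neither field, reproducing the snapshot's
published 1555-row total whose marginal counts sum to only 1554 (the reader
rejects and counts such rows rather than resolving them).

What the stand-in does *not* emulate: the true depth distribution's exact
quantiles away from the calibrated 0.5 m point, depth–area dependence
(fields are paired at random), temporal trends, and any recording
discreteness (real depths cluster on round centimetres). Tests passing on
the stand-in therefore validate the machinery and the calibrated marginals,
not conclusions about the real registry beyond those marginals.

CSV round trips write depth in whole centimetres, bounding the round-trip
perturbation at 0.005 m; a handful of the stand-in's borderline depths land
on exactly 0.50 m after rounding, so exact-tail checks use the in-memory
records.

## Numerical and design choices

- Quantiles everywhere are numpy's linear-interpolation convention
  (type 7).
- Missing table cells are represented as absent, never 0; non-positive or
  non-numeric measurements are treated as absent on ingest.
- Depth unit conversion (cm → m) happens once, on ingest; all computation
  is in metres and minutes.
- The probing-depth grid is 0.5–2.5 m in 0.1 m steps (21 points); the CPR
  grid is 0–30 min in 1-min steps (31 points).
- The default rescuer policy assigns 5 rescuers to deposits ≤ 1000 m²
  (companion rescue) and 20 to larger ones (organized rescue); both the
  5000 m² scenario with 5 and with 20 rescuers are meaningful, and the
  sweep accepts a fixed crew or any callable policy.
- Negative Gaussian search-time draws are truncated to zero (about 2.3% of
  draws at the default mean 2, sd 1), matching the censored-normal moments
  the tests check against.
- CLI result probabilities are written with 6 significant digits; equality
  comparisons are the job of tooling, not formatting.

## Problem sizes

Default fits use 10,000 runs per grid point; the full default area sweep
(six areas × 21 depths) and the three-case burial-time sweep run in
well under a minute on one CPU, and the test suite uses 2,000–20,000 runs
per check. These sizes put Monte Carlo standard errors well below every
margin the tests assert; larger runs only tighten diagnostics.

## Known limitations

- No cooling/hypothermia model: patient 1 is assumed normothermic, which is
  realistic within the first hour of burial; staged hypothermic protocols
  are out of scope.
- The ROSC curve shape comes from out-of-hospital cardiac-arrest patients
  whose arrests were not hypoxia-triggered; for avalanche victims the true
  curve may rise more steeply, which would shorten the optimal CPR time.
- One rescuer, two patients in the triage scenario; one buried subject and
  no lateral miss probability in the probe scenario.
- All optimum locations are conditional on the curve digitization. With
  curve `v1` and the stand-in data, the 5000 m² / 20-rescuer probing
  optimum sits near 1 m (flatter and shallower than older published
  analyses of the same scenario, which reported ~1.9 m with a different
  curve digitization and the real registry depths); the CPR optimum for the
  12-min case sits at 10–11 min.
- At large areas with large crews the survival-vs-probing-depth profile
  becomes very flat near its maximum, and the estimated optimum can
  plateau or move up one 0.1 m grid step between 5,000 and 10,000 m²
  (profile differences ~2·10⁻⁴). The "deeper areas, shallower probing"
  monotonicity is crisp at a fixed 5-rescuer crew across 50–10,000 m²,
  and that is the setting the structural tests assert.
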