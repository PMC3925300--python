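# Methods

## Model structure and assumptions

The simulator is an individual-based model of female Medfly only; males,
genetics, space and movement are out of scope.  Time advances in 1-h steps
driven by an ambient temperature series; within each hour every live agent
is offered, in order, a stage transition, reproduction (at the daily
reproduction hour), a natural-death trial, and — after countermeasures
begin — a human-induced-death trial.  Dead agents are removed immediately.
Eggs laid during an hour join the population at the end of that hour and
face their first trials the following hour.  Agents are stored column-wise
in numpy arrays and all stochastic decisions draw from a single per-run
generator, so runs are reproducible for a fixed seed and fast enough for
10³–10⁴-run parameter sweeps on one CPU.

### Development

Thermal-unit mode (default): each hour contributes
max(0, T − T_min,x) degree-hours, zero above T_max (development halts in
extreme heat).  The per-individual threshold is 24·K_x·(1 + γz), redrawn at
each stage entry; K_x is tabulated in day-degrees, and the factor 24 keeps
the hourly sum dimensionally consistent.  Accumulation in excess of a
threshold carries into the next stage, avoiding a systematic truncation
bias of up to one hour per stage.  Adult maturation (immature → mature) is
modeled identically via T_min,a / K_a.  The alternative hourly-probability
mode makes the transition memoryless with per-hour probability
increment/(24K), matching the thermal-unit mode's mean duration at constant
temperature while adding geometric variance.

### Reproduction

Fertile mature females lay round(N(r, r_var)) eggs once per day, clamped at
zero; a binomial female_fraction (default 0.5) of them become agents, since
the model tracks females only and literature fecundities do not state
whether they count daughters.  After t_S: new offspring are instantiated
sterile by default (they live, develop and die but never reproduce),
reflecting host-fruit removal; the INHERIT policy instead lets them breed
subject to the same rules as their dams.  Each fertile mature female also
faces a daily probability r_red of permanent fertility loss, the
sterile-male-mating effect.  Fertility loss is tested at the reproduction
hour, after that day's laying.

### Mortality

Temperature-dependent mode (default): daily mortality is
clamp(M*_x + μ_x(T), 0, 1) with upward-opening quadratics

    μ_e,l(T) = 0.00040T² − 0.0145T + 0.1314
    μ_p(T)   = 0.00050T² − 0.0207T + 0.2142
    μ_a(T)   = 0.00049T² − 0.0187T + 0.1846

clamped to [0, 1] (the egg/larva and pupa curves bottom out marginally
below zero at their vertices; clamping makes the optimum contribution
exactly zero, which is why the composition with the baseline M* is
additive rather than multiplicative).  Daily rates convert to hourly
trial probabilities by survival compounding, 1 − (1 − M)^(1/24), so 24
independent hourly trials reproduce the daily rate to machine precision.
The historical per-hour rule M^(1/24) is available behind
`literal_hourly_exponent` for archaeology only: it yields per-hour
probabilities far above the daily rate and contradicts the daily-rate
semantics.  A fixed per-stage mode (M_x, no temperature dependence) is
used for the Leslie validation.

## Key parameters

| Symbol | Meaning | Unit | Default / range |
|---|---|---|---|
| T_min,x | base developmental temperature | °C | literature ranges, e.g. egg 9.6–12.5 |
| K_x | thermal constant per stage | day-degrees | e.g. egg 27.27–33.80 |
| T_max | development ceiling | °C | 35 |
| γ | SD of threshold as fraction of mean | – | 0.05 |
| M*_x | daily mortality at thermal optimum | /day | e.g. pupa 0.0016–0.0465 |
| r, r_var | daily eggs per female: mean, variance | eggs | 5–35, 3.57 |
| r_red | daily fertility-loss probability after t_S | /day | 0.5–1.0 |
| S | extra daily adult mortality after t_S | /day | 0.005–0.050 |
| t_S | delay to countermeasures | days | per outbreak (2–21) |
| N_m | live-agent cap | insects | 10⁶ |

Defaults for point runs are literature-range midpoints; sweeps draw from
the full ranges by Latin hypercube sampling (one uniform draw per equal
stratum per parameter, columns permuted independently).  γ, T_max and
r_var are held fixed across sweeps.

## Initialization from trap captures

N_0 = (flies found in first 3 days / trap sensitivity) × female share;
total population = round(N_0 / 0.012), split across stages by the stable
age distribution (0.436, 0.403, 0.137, 0.012, 0.012) with the rounding
residual assigned to the largest compartment.  With sensitivity 0.02–0.03
this reproduces the published per-outbreak N upper bounds exactly (6250,
4167, 2083 for 3/3/1 flies); two published lower bounds (1375, 2760)
differ by ~1 % from the clean reconstruction (1389, 2778), an intermediate
rounding in the original we deliberately do not force.  Within a stage,
initial progress is Uniform[0,1) of the individual threshold — a point
mass at stage entry would cause synchronized molting artifacts.  flies
found are not split by sex before scaling; the halving happens once via
the female share.

## Temperatures

Hourly CSVs are reindexed to a contiguous hourly grid with explicit
missing flags.  Missing hours are reconstructed from daily extremes with
the two-term Fourier diurnal shape Γ(t) (ω = π/12 for 24-h periodicity; a
printed source drops the numerator, and π/12 is the value consistent with
the cited interpolation method), pairing early hours with the previous
day's maximum and evening hours with the next day's minimum; at series
edges the same day's value substitutes (bias confined to 11 edge hours).
Γ is applied verbatim without clamping, so reconstructed hours can
overshoot the daily extremes by a few percent; hour 0 uses the evening
branch shape, continuous with hours 1–5.  Partially observed days are not
special-cased: gap-filling requires complete daily extremes for every day
containing a missing hour.

## Synthetic temperature generator

`synthesize_fixture` emulates the structure the simulator cares about:
a sinusoidal diurnal cycle between daily extremes, small day-to-day normal
jitter (SD 0.8 °C), and optional cold snaps that depress both extremes.
The bundled scenarios are `warm` (120 days, 15/28 °C — a Southern-
California-like late-summer regime), `cold_snap` (the same series with a
3-day hard freeze at day 45: depth 28 °C gives extremes −13/0 °C so the
snap days are genuinely sub-zero, not just night frosts), and
`leslie_constant` (constant 24 °C).  The generator does **not** emulate
seasonal trends, heat waves, humidity, or station measurement error, so
passing tests demonstrate correct model mechanics under controlled
forcing, not predictive skill for any real outbreak — replicating a real
outbreak requires the station's hourly export.

A noteworthy model behavior found while building the cold-snap fixture:
a mild snap (night frosts around −3 °C with warm afternoons) slightly
*lengthens* simulated extirpation, because stalled development outweighs
the modest extra mortality, while a hard freeze shortens it sharply.  Both
regimes lengthen the degree-day quarantine, so the qualitative contrast
between the stochastic and degree-day views holds only for genuinely
sub-zero spells — consistent with the observation that at least several
hours below 0 °C are needed for the mortality channel to dominate.

## Experiment layer

Batches run one simulation per LHS row with per-run seed = base + row
index (deterministic and embarrassingly parallel).  t_m averages t_e over
extirpated runs; t_q is the smallest day by which ≥ q of *all* runs have
extirpated, with censored (temperatures-exhausted) runs counted as not yet
extirpated — conservative, and t_q is undefined if fewer than q ever
extirpate.  PRCC rank-transforms all columns, correlates the residuals of
each input and the response after regressing both on the remaining inputs,
and reports t = ρ√((N−2−k)/(1−ρ²)) with a two-sided t-test; p-values are
raw (no multiplicity correction), and by default only extirpated runs
enter.  The initial population enters the sweep through trap sensitivity
(sampled 0.02–0.03), and the derived N_0 column is what the PRCC table
reports.  The degree-day quarantine comparator accumulates
max(0, T − T_min)/24 day-degrees per hour until `generations ×
K_generation`; K_generation defaults to K_e+K_l+K_p+K_a at range midpoints
(≈ 399.9 day-degrees) with T_min the mean of the stage base-temperature
midpoints (≈ 9.8 °C), both configurable since regulatory constants vary by
jurisdiction.

## Leslie validation

Under constant 24 °C, fixed daily mortalities (M_e = 0, M_l = 0.6,
M_p = 0.2, M_a = 0.15) and constant fecundity, the agent model is compared
with a 40-age-class Leslie projection started from 100 mature females.
Age classes per stage follow the durations the developmental constants
imply at 24 °C — egg 2, larva 10, pupa 12 — with 5 immature-adult classes
so mature adults begin at class 30.  The published parameter list labels
the constant 124.0 as the adult one while omitting the pupal constant; we
assign 124.0 to the pupa (it yields exactly the ~12-day pupal duration the
40-class layout implies) and give adult maturation 5 days at 24 °C
(K_a = 75.5, T_min,a = 8.9).  Either assignment is configurable.

Two alignment choices matter and are made once, on first principles:

- **Census phase.**  The daily Leslie operator implicitly spreads births
  and deaths through the day; the hourly model resolves them.  Laying eggs
  at the midday hour (the config-exposed reproduction hour) rather than
  midnight halves the census-phase offset between the two bookkeeping
  conventions; without it the larval proportions disagree by ~0.09
  systematically, with it by < 0.05.
- **Fecundity.**  The published parameter list pins no fecundity.  With
  100 mature females and any realistic daily fecundity, the initial egg
  pulse transiently *raises* total abundance for both methods, so "totals
  decline monotonically" — the demographic trend the validation is meant
  to show — would not hold.  The validation scenario therefore uses a net
  fecundity of 0.1 female eggs/female/day, realized as r = 1 egg/day
  thinned by female_fraction = 0.1 so the per-female draw stays
  integer-valued and its mean exact; the Leslie first row carries the same
  0.1.  Stage-proportion agreement, which is what validates the engine's
  transition and mortality bookkeeping, does not depend on this choice.

After day ~10 the comparison degrades by construction: the 40-class matrix
truncates its initial adults at class 40 (day 11), which the agent model —
with no maximum age — does not reproduce; the scored window is days 1–10.

## Numerical and engineering choices

- t_S is compared in whole hours (t_S × 24) from simulation start; day
  boundaries are simulation-relative 24-h blocks, not calendar midnight.
- Extirpation requires *all* agents dead (matching "until all agents are
  dead"); a fertile-only variant exists behind a flag, off by default.
  t_e = ⌈hours/24⌉ at the first agent-free hour; an empty initial
  population gives t_e = 0.
- Hitting the N_m cap truncates that day's new eggs and flags the run;
  the run continues, and the flag surfaces as the termination reason only
  if the run never extirpates.
- Threshold draws are redrawn until positive (only relevant for γ ≫ 0.05);
  egg counts clamp at zero, which biases the mean upward only when
  r ≲ 2 SD, far below the swept range.
- Batch failures are recorded per-row and never abort a sweep.
- Problem sizes in tests and the acceptance script (100 Leslie replicates,
  2000- and 1000-run sweeps, 200 cold-snap pairs, 240-day synthetic
  series) were chosen so every Monte-Carlo margin is several standard
  errors wide at desk scale.

## Known limitations

- No space, movement, male flies, density dependence, host-fruit dynamics,
  or trap-grid geometry; the trapping model is a single sensitivity.
- The quadratic mortality curves are extrapolated below 0 °C and above
  35 °C only through clamping to [0, 1].
- The hourly-probability development mode matches means but not the
  variance structure of the thermal-unit mode; all validation uses the
  thermal-unit mode.
- Real-outbreak replication depends on station data the package does not
  ship; nearest-station distance (up to ~20 km in the original analyses)
  is an unmodeled error source.
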