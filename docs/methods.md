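# Methods

This note documents the modelling choices behind `pharmdyn`: what is
simulated, which functional forms and constants were chosen where the
source system is documented only qualitatively, and what the validation
suites do and do not establish.

## 1. Scope and approach

The package follows the standard SD workflow: articulate the problem
(pharmacy profitability vs. medication waste), encode the dynamic hypothesis
as a signed causal-loop diagram, translate it into a stock-and-flow model,
test the model (structure, parameter, boundary-adequacy), and evaluate
policies by parameter overrides. The simulation horizon is 24 months with a
forward-Euler step of 0.25 months; both are configurable.

## 2. Causal-loop diagram

The domain evidence names 17 sustainability challenges, types them (10
cause, 7 effect), states that they form 8 feedback loops, and narrates two
of them: the balancing loop B1 (poor emergency responsiveness → incorrect
procurement prioritization → weak consumption analysis → liquidity and
profitability problems → personnel recruitment) and the reinforcing loop R1
(no certified financial manager → inadequate liquidity management → weak
cost-profitability analysis → no financial manager). The full signed edge
list is not published, so `data/reference_nodes.csv` and
`data/reference_edges.csv` are a **reconstruction**: 24 signed edges chosen
so that the named loop narratives hold verbatim, the node/role counts match,
and exactly 8 simple directed cycles exist.

One narrative required a sign decision. Read literally, B1 is a chain of
"bad worsens bad" links, which would make it reinforcing, contradicting its
B label. The reconstruction interprets the final link as a corrective
managerial response: financial strain raises recruitment *pressure*, and
recruitment activity *reduces* poor emergency responsiveness (one negative
edge, hence balancing). This is the package's documented resolution of an
ambiguity in the source material.

Loop enumeration uses `networkx.simple_cycles`; cycles equal up to rotation
are one loop (canonicalized to start at the smallest node id) and a cycle
and its reverse are distinct. Loop polarity is the parity of negative edges.

## 3. Stock-and-flow engine

* **Integration.** Fixed-step forward Euler. All flows and auxiliaries are
  evaluated synchronously from the time-`t` state in one topological pass
  (the algebraic dependency graph must be acyclic), then all stocks update.
  Declaration order never affects results.
* **Non-negativity.** Stocks representing physical goods are flagged
  `non_negative`: when a step would overdraw such a stock, its outflows for
  that step are scaled down proportionally so the stock lands exactly at
  zero, and the *scaled* flow values are recorded, keeping per-stock
  accounting exact. The money stock (profit) is not flagged and may go
  negative. A flow may drain at most one stock so the scaling is
  unambiguous. In floored regimes, money flows computed upstream of the
  scaling are not re-evaluated; the reference calibration and all shipped
  scenarios stay away from the floor (saturating sales forms make the
  equilibria interior).
* **Accuracy.** Forward Euler is first order: halving `dt` halves the
  error (asserted on the exponential-decay model). For a decay at rate
  0.5/month over 24 months the signed relative endpoint error is
  `rate² · t · dt / 2` — about 4.7 % at `dt = 1/64` — so integrator accuracy
  statements are made in sup norm relative to the initial stock (0.14 % at
  `dt = 1/64`) rather than relative to the vanishing endpoint.
* **Conservation.** `check_conservation` re-integrates every stock from its
  recorded flows with a tolerance accumulating at relative 1e-9 per step.
* **Units** are declared strings, checked for presence only; no
  dimensional algebra.

## 4. Pharmacy model equations

The source material specifies influence structure and trajectory shapes but
no equations; the algebra below is this package's calibrated reconstruction.
Units are abstract (MU = money units, packs); no real prices or wages are
claimed. Calibration constants live at the top of `pharmacy_model.py`.

* **Service level.** `response_speed = response_speed_base ·
  competence^0.5 · (1 + 0.25 · pharmacists_in_team)`. The reference
  calibration normalizes this to 1.0 (diminishing returns to competence;
  each team pharmacist adds 25 %).
* **Adjustment cost.** `service_adaptation` is a first-order smooth of
  `response_speed` (time constant `accuracy_adjust_time`, initial value = the
  normal service level 1.0). While `gap = max(0, response_speed −
  service_adaptation)` is positive, profit pays `350 · gap² /
  mitigation` MU/month, with `mitigation = competence³ · (1 +
  0.25·pharmacists)/1.5` (reference = 1). The quadratic makes small service
  improvements nearly free while a doubled raw speed is initially costly;
  the mitigation term encodes that competence- and pharmacist-backed
  speed-ups come with the skills to absorb them. Together these reproduce
  the documented scenario behaviours: a transient profit dip only when
  response speed alone is doubled.
* **Expiring (low-consumption) medicines.** Inflow `expiry_inflow_base +
  resident_overprescription_coeff · residents` (unnecessary resident
  prescribing feeds the expiring shelf). Outflows: sales
  `55 · response_speed · S/(S+30)` packs/month (saturating — service, not
  shelf volume, limits sales at scale), inter-pharmacy transfer
  `transfer_rate_coeff · S`, and disposal `expiry_fraction · S /
  (1 + transfer_rate_coeff)` — an active exchange programme diverts items
  that would otherwise expire, which realizes the documented mutual
  influence of expiring stock, disposal and the exchange rate between
  pharmacies. Because disposal is proportional to a growing stock,
  cumulative waste accelerates.
* **Initial sales surge.** A backlog stock (60 packs) of pre-study unfilled
  low-consumption orders clears with a 0.8-month time constant, producing
  the documented surge in early sales. Backlog goods are accounted outside
  the expiring shelf so the surge does not force an early dip in
  `total_expiring_medicines`, which instead stays flat for the first two
  months (it starts at its quasi-equilibrium for the initial resident
  census) and then rises as the census grows.
* **Residents.** Constant intake; graduation `residents /
  residency_duration`. The census relaxes toward `intake · duration`,
  slowly raising the expiring inflow — the engine of the accelerating waste
  and decelerating profit shapes.
* **High-consumption medicines.** Seasonal demand `base · (1 + amplitude ·
  sin(2πt/period))`; sales `demand · inv/(inv+100)`; orders
  `share · monthly_purchase · (1 + 1.5 · response_speed · (1 − inv/target))`
  with `target = 2 · base demand`, fed through a first-order material delay
  of `order_delay` months (in-transit pipeline initialized at its t = 0
  steady state). Buying and selling therefore oscillate with the demand
  season — the sinusoidal shapes are demand-driven by design, which is
  robust, rather than relying on a purely endogenous delay-loop oscillation.
* **Money.** Profit inflows: low-consumption sales ·
  `avg_price_low · profit_margin_low` and high-consumption sales ·
  `avg_price_low · profit_margin_high`. The parameter schema carries a
  single average pack price; the two classes differ in margin. Outflows:
  disposal cost (`disposal_rate · disposal_unit_cost`), wages
  (`avg_salary · staff_count`), overhead, and the adjustment error cost.
  Inter-pharmacy transfers move goods at cost and contribute no profit.

### Reference calibration

`reference_parameters()` encodes a mid-sized inpatient pharmacy:
20 residents growing toward 36 (intake 1.5/month, 24-month residency),
300 packs of expiring stock (its quasi-equilibrium at t = 0), 900 packs of
high-consumption inventory against a base demand of 400 packs/month with a
20 % seasonal swing of period 6 months, margins of 25 % (slow movers) and
15 % (fast movers), and fixed costs of 380 MU/month. Values were chosen
analytically (equilibrium and time-scale arguments as sketched above) and
verified by simulation before being frozen; the reference service level is
normalized to exactly 1 so that the baseline pays no adjustment cost.

## 5. Scenarios

Overrides are multiplicative step changes at t = 0 to constants only —
initial stocks are never overridden, so scenarios share the baseline's
starting state. S1: competence ×2. S2: response_speed_base ×2. S3:
pharmacists_in_team ×0.5. S4: competence, response base and pharmacists all
×2 (the combined-improvement scenario mirrors S3's halving as a doubling).
Comparison reports give endpoint deltas, dominance fractions (strict
inequality, ties excluded, t > 0 only) and linearly interpolated
sign-crossing times; "the first few months" for S2's dip is operationalized
as a single crossing within (0, 6] months.

## 6. Trend classification

Series are resampled to integer months (nearest grid point) before
classification so labels do not depend on `dt`. With `x` on `[0, T]` and
`tol = 1e-6 · range`: *increasing* — `x(T) > x(0)` and all monthly
differences ≥ −tol; *accelerating* / *decelerating* — ordering of the
half-interval changes, both positive; *initially flat* — `|x(2) − x(0)| ≤
0.05 |x(T) − x(0)|`; *initial surge* — mean slope on [0, 2] exceeds that on
[2, T], both positive; *oscillatory* — ≥ 2 strict local maxima and minima
after removing the least-squares line; *constant* — range ≤ 1e-9 ·
max(1, max|x|). The 2-month early window and 5 % flatness share mirror the
documented "first two months" phrasing. Labels are invariant under positive
affine rescaling away from the degenerate near-constant corner (property
tested).

## 7. Validation suites

* **Structure verification** diffs every flow/auxiliary's `depends_on`
  against `influence_table()`, an explicit literal maintained separately
  from the model builder. The table records *direct* dependencies; drivers
  that act through a named intermediate (e.g. pharmacists act on sales via
  `response_speed`; response speed acts on buying via `order_rate_high`)
  are captured at that intermediate rather than repeated downstream.
* **Parameter verification** checks hard valid ranges (failing) and the
  packaged plausible ranges (informational only, since legitimate scenario
  overrides leave the plausible band).
* **Boundary adequacy** drives the resident pipeline to zero three ways:
  zero intake (census must decay monotonically, within 1 % of
  `R0·e^(−t/duration)`), zero intake with a 1e6-month residency (census
  constant; the near-infinite duration keeps division safe), and zero
  residents (resident-driven expiring inflow vanishes; expiring stock grows
  strictly more slowly than baseline).

## 8. Synthetic cohorts

`synthetic_params` samples each field independently from
`data/parameter_ranges.json` — roughly ±25 % around the reference,
log-uniform for strictly positive scale parameters and uniform for
fractions/indices — using splitmix64-derived sub-seeds per cohort member.
The generator emulates between-pharmacy heterogeneity in scale and rates; it
does **not** emulate correlation structure between parameters, measurement
error, or non-stationary behaviour, so ensemble results speak to parametric
robustness of the model, not to real-world variability. The committed
robustness statement is that ≥ 80 % of a 50-member sampled cohort shows
increasing cumulative disposed medicines; in practice the fraction is 1.0.

## 9. Problem sizes and determinism

Default runs are 97 time points (24 months at `dt = 0.25`); integrator
accuracy checks use up to 1536 steps; cohort analyses use 16 (reproducibility)
and 50 (robustness) members. Everything completes in seconds. Simulation is
deterministic given (model, parameters, config); randomness enters only
through parameter sampling, which is fully seeded.

## 10. Known limitations

* Functional forms and calibration constants are the package's own; only
  influence structure, trajectory shapes and structural counts are sourced.
  No numeric agreement with any external run is claimed or checkable.
* Sensitivity analysis beyond the boundary-adequacy limits is out of scope,
  as is per-drug granularity, multi-pharmacy network flow, and real price
  data.
* Forward Euler only; stiff parameterizations (time constants ≲ `dt`) need
  a smaller step, which `SimConfig` allows but nothing enforces.
* The causal graph is a reconstruction; alternative edge sets could satisfy
  the same published counts and narratives.
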