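# pharmdyn

System-dynamics (SD) modelling of the **sustainable drug supply chain in
hospital inpatient pharmacies**: a causal-loop diagram of the sustainability
challenges the sector faces, a stock-and-flow simulator of one pharmacy's
drug, staff and money flows over 24 months, validation suites (structure,
parameter and boundary-adequacy tests), and four policy scenarios that probe
workforce competence, response speed and pharmacist involvement in
prescribing.

The package is aimed at health-systems and supply-chain researchers who want
a reproducible, scriptable alternative to GUI-based SD tools for this class
of pharmacy model.

## The model in brief

A causal-loop diagram encodes 17 supply-chain challenges (insufficient
specialized staff, poor emergency responsiveness, unnecessary resident
prescribing, weak financial analysis, medication expiration, ...) as a
signed digraph with 10 cause-type and 7 effect-type nodes forming 8 feedback
loops. A loop with an even number of negative links is *reinforcing* (R),
with an odd number *balancing* (B); the named loops are the balancing
emergency-response → procurement → finance → recruitment loop **B1** and the
reinforcing financial-manager → liquidity → cost-analysis loop **R1**. The
published diagram does not print its edge list, so the packaged graph is a
documented reconstruction that realizes the loop narratives and counts.

The quantitative model is a stock-and-flow system integrated by forward
Euler (default `dt = 0.25` months over 24 months). Stocks `S` evolve as

```
S(t + dt) = S(t) + dt * (Σ inflows(t) − Σ outflows(t))
```

with physical stocks floored at zero by proportional outflow scaling. The
pharmacy model tracks pharmacy profit, the resident census, expiring
low-consumption medicines, cumulative disposed medicines and their cost, and
the inventory of high-consumption medicines, with standard SD primitives —
first-order smooths (`dY/dt = (X − Y)/T`) for staff adaptation and
first-order material delays (`arrivals = in_transit / delay`) for the order
pipeline. Because the original per-pharmacy survey data are unpublished, a
seeded synthetic generator samples plausible parameter sets for cohort-level
robustness runs.

## Worked example

```python
from pharmdyn.pharmacy_model import reference_parameters, build_pharmacy_model
from pharmdyn.sd_engine import SimConfig, simulate
from pharmdyn.validation_patterns import classify_trend

params = reference_parameters()
traj = simulate(build_pharmacy_model(params), params.to_dict(), SimConfig())
for name in ("pharmacy_profit", "total_disposed_medicines"):
    print(name, round(traj.at(name, 12.0), 2), round(traj.at(name, 24.0), 2))
print(sorted(classify_trend(traj["total_disposed_medicines"], traj.times)))
```

prints

```
pharmacy_profit 2455.18 4528.58
total_disposed_medicines 223.42 499.28
['accelerating', 'increasing']
```

Profit (in abstract money units) grows by about 2455 MU in the first year
but only about 2073 MU in the second — growth decelerates as disposal costs
mount — while cumulative disposed medicine accelerates: 223 packs are wasted
in the first year and 276 in the second. The classifier turns such shapes
into labels (`increasing`, `accelerating`, `oscillatory`, ...) that the
validation suite asserts.

The same pipeline is scriptable from the shell:

```bash
pharmdyn loops --reference            # causal-graph structure report (JSON)
pharmdyn simulate --reference --out run.csv
pharmdyn scenarios --reference --out-dir runs/
pharmdyn validate --reference         # exit 0 iff all validation suites pass
pharmdyn sample-params --n 16 --seed 7 --out cohort.csv
```

## Policy scenarios

`pharmdyn scenarios` compares a baseline run against four step-change
policies applied at t = 0: **S1** doubles workforce competence, **S2**
doubles base response speed (profit first dips during the staff adjustment
period, then overtakes the baseline within a few months while the stock of
expiring medicines falls), **S3** halves the pharmacists in the prescribing
team (profit drops below baseline throughout), and **S4** combines
competence, speed and pharmacist doubling (dominates the baseline at every
time point and ends highest).

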