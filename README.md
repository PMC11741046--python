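# carbonledger

Systemic carbon mass-balance accounting for complex, integrated production
systems — livestock farms, farm consortia and similar agro-ecosystems whose
productive processes (herds, crops, soils, energy use) exchange materials
with each other as well as with the outside world.

Product-oriented assessment methods such as LCA evaluate one production
process at a time and largely ignore these internal exchanges. A
whole-system mass balance takes the opposite view: every material and energy
flow is expressed as carbon mass and booked as a directed flux between five
*sites* — the system pools **animal**, **plant** and **soil**, and the
boundary pools **air** (atmosphere) and **external** (market). The flux
category follows from its endpoints alone:

* boundary → system: **input** (I)
* system → boundary: **output** (O)
* system → system: **internal** (N) — tracked, but cancelling

and the net systemic carbon balance over the accounting period is

```
B = Σ inputs − Σ outputs        (t C; B > 0: the system accumulates C,
                                 B < 0: it depletes its stocks)
```

with derived indicators: per-site gross storage, the net exchange with the
atmosphere (negative when the system removes C from the air), the carbon
efficiency `B / Σ inputs`, the carbon intensity `Σ inputs / FU` for a chosen
functional unit FU (hectares of utilised area, tonnes of slaughtered live
weight, ...), and per-FU rates for every flux. A two-way sensitivity
analysis perturbs the pooled input and output totals by their
amount-weighted variation ranges and reports whether the sign of the
balance survives the worst corner.

The package provides the flux-ledger data model and validator, a registry
of stoichiometric carbon-conversion coefficients (0.27291 for CO2, 0.74882
for CH4, 0.50 for plant material, ...), the enteric-emission-by-difference
estimator for ruminant herds, the balance and index computations, the
sensitivity analysis, CSV ledger I/O, DOT flowchart export, structured and
tabular reports, a seeded synthetic-ledger generator, and a small CLI. It
ships the published whole-consortium beef-farm validation case
(≈1300 Piedmontese farms, one year, fluxes in 10³ t C) as a packaged
dataset.

## Worked example

```sh
carbonledger fixture --out coalvi.csv   # the packaged consortium ledger
carbonledger balance coalvi.csv
```

prints

```
system:        Coalvi beef-farm consortium (1 year)
total inputs:  379.0 10^3 t C
total outputs: 295.7 10^3 t C
balance:       83.3 10^3 t C
air change:    -96.1 10^3 t C
storage animal: 8.6 10^3 t C
storage plant: 109.3 10^3 t C
storage soil: 0.0 10^3 t C
efficiency:    0.2198
intensity (utilised agricultural area): 5.37 10^3 t C per 10^3 ha
intensity (LW slaughtered): 10.18 10^3 t C per 10^3 t LW
```

The consortium stores 83.3 × 10³ t C in a year (about 22 % of its carbon
inputs) and removes 96.1 × 10³ t C from the atmosphere — plant uptake of
357.4 against 261.3 released as animal, manure, fuel and soil gases. Most of
the stored carbon accumulates in the plant pool (109.3), a little in the
animals (8.6), and the soil is in equilibrium (0.0). Per functional unit the
balance is 1.18 t C ha⁻¹ of utilised area and 2.24 t C per tonne of
slaughtered live weight. The same numbers are available from Python:

```python
import carbonledger as cl

ledger = cl.datasets.coalvi()
report = cl.compute_balance(ledger)
report.balance          # 83.3 (10^3 t C)
report.air_change       # -96.1
```

`carbonledger sensitivity coalvi.csv` pools the per-flux variation ranges
(±10 % on both sides here) and reports the corner scenarios:

```
deltas:     ±10% inputs, ±10% outputs
centre:     83.3 10^3 t C
worst case: 15.8 10^3 t C
best case:  150.8 10^3 t C
sign robust: yes
```

Even in the worst corner (inputs −10 %, outputs +10 %) the balance stays
positive: the conclusion that this system is a net carbon sink is robust to
the flux uncertainty. Other subcommands: `validate`, `flowchart` (DOT
export, solid/dashed/dotted edges for I/O/N), `report` (JSON or the
table layout of the source study), `generate` (seeded synthetic ledgers).

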