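# Methods

## The accounting model

The system is partitioned into five carbon sites: three *system* pools
(animal, plant, soil) and two *boundary* pools (air, external market). A
ledger is an ordered collection of directed fluxes, each a nonnegative
carbon mass per accounting period (one period per ledger; the validation
case uses one year). Direction is carried exclusively by the (source, sink)
pair; the conventional sign (+ for inputs, − for outputs) is applied only
when reports are rendered, which keeps conservation checks trivial and
prevents double-negation errors.

The flux category is a function of the endpoints — boundary→system = input,
system→boundary = output, system→system = internal; a boundary→boundary
pair never crosses the system and is rejected. The declared category of
every record is re-derived and checked by the validator, which collects
violations (per flux id and rule) rather than raising, so one pass reports
every problem in a file.

The net balance is `Σ inputs − Σ outputs`; internal fluxes cancel exactly,
which is property-tested. Fluxes are summed with compensated summation
(`math.fsum`), so the residuals of the reconciliation identities are at
floating-point noise level (≤ 1e-13 on thousands of random ledgers) against
a pass tolerance of 1e-6 relative.

## Sector attribution

Each flux carries a `sector` tag (animal / plant / soil) naming the
productive sector it is attributed to. The tag is reporting metadata only
and never enters the arithmetic. Internal fluxes are stored once
(source → sink) with the source site's sector; the tabular report re-expands
each internal flux into both the sending block (negative) and the receiving
block (positive), which reproduces the published 17-row presentation from
the 14 distinct fluxes.

## Conversion coefficients

The registry seeds the standard livestock-farm coefficient set: C mass
fractions 0.27291 (CO2), 0.74882 (CH4), 0.19998 (urea, CH4N2O), 0.46
(protein), 0.70 (fat), 0.40 (carbohydrate, CnH2nOn), 0.36 (urine), 0.50
(plant material, from the average formula CH1.44O0.66); 723.2 g C/L for
fuel oil on a volume basis; live weight bounded to [0.15, 0.20] with **no
default point value** (the fraction is breed-specific and must be
configured; values outside the band warn but are accepted); electricity on
an energy basis with no default (the kg C/kWh factor depends on the national
generation mix). Units form a closed set (g, kg, t, L, m³, kWh) with fixed
factors to tonnes C — no general unit-algebra dependency.

The literature values are stored verbatim and are authoritative;
`check_stoichiometry` recomputes each gas fraction from standard atomic
masses (C 12.0107, O 15.9994, H 1.00794, N 14.0067) and reports deviations,
flagging anything above 2×10⁻⁴. The registered CH4 value 0.74882 deviates
from the exact 0.74868 by ≈1.4×10⁻⁴ — within tolerance, reported, not
corrected.

## Enteric emissions by difference

Enteric gas carbon is estimated as the closure of the herd budget:
`feed − retention − milk − calves − respiration − excreta`. Calves are
booked as a separate output, not inside live-weight retention. A negative
closure raises an inconsistency error naming the shortfall; a valid account
partitions feed carbon exactly (relative tolerance 1e-9 in tests). The many
other derived quantities a practitioner needs (crop residues, manure,
fuel-per-operation, NEE, ...) are supported only through the generic
`coefficient_product` with a provenance trace — their coefficients and
models are sector-specific and belong to the analyst.

`variation_range` estimates a variable's most probable half-range as
100·(max − min)/(2·mean). The estimator is a convention (no standard one
exists for "most probable range"); a coefficient-of-variation alternative
is available via `mode="cv"`. It is scale-invariant, which is
property-tested.

## Site storage (reconstructed convention)

The published table prints per-site storage values without a formula. The
convention adopted here — **biogenic inflows minus biogenic outflows to
other system sites or to air**, i.e. market exports remain in the pool
until sold and fossil-flagged fluxes never enter a biomass pool — is the
reconstruction that reproduces all three printed values exactly
(plants 109.3, animals 8.6, soil 0.0 in 10³ t C), including the soil pool
closing at exactly zero only if fertiliser carbon (urea) counts as a soil
inflow. It is a reconstruction, not a published definition, and is the
falsifiable part of the conventions; the identity

```
balance = Σ site storage − biogenic exports + fossil inputs − fossil outputs
```

is checked by `reconcile` on every report (83.3 = 117.9 − 34.4 + 15.6 −
15.8 on the validation case). Fossil fuel is modelled as the paired
pass-through external→plant and plant→air (15.6 in, 15.6 out), which keeps
it visible in the totals while identifiable for exclusion from the pools.

One printed value is knowingly not reproduced: the air-site row per tonne
of live weight appears as +2.58 in the source table while its total and
per-hectare entries are negative (−96.1, −1.36). The package reports
−2.58 — the sign convention (negative = net removal from the atmosphere)
applies to every column; the printed positive entry is treated as a typo.

## Functional units

The validation case's FU denominators are not printed; they are implied by
the table's row ratios, taken from the largest row (net plant exchange,
357.4): utilised agricultural area = 357.4/5.06 = 70 632 ha and slaughtered
live weight = 357.4/9.60 = 37 229 t LW, stored on the same 10³ scale as the
flux amounts. With these denominators every per-FU entry matches the
printed table at its 2-decimal rounding, and the balance per FU is
1.18 t C ha⁻¹ and 2.24 t C t⁻¹ LW.

## Sensitivity analysis

The pooled variation of each category is the amount-weighted mean of its
components' half-ranges (`Σ aᵢvᵢ / Σ aᵢ`), rounded half-away-from-zero to
the nearest integer percent by default, as the validation study did
(±10.4 → ±10, ±9.9 → ±10). The two-way analysis applies uniform multipliers
1±δin to all inputs and 1±δout to all outputs — internal fluxes are left
untouched; they cancel in the balance, so the choice is immaterial — and
evaluates the four corners plus the centre (`grid_points` refines each axis
if wanted). The component-level ranges behind the published ±10 % are not
printed, so the packaged fixture carries a uniform 10 % per flux, making
the pooled value 10 % identically; the weighting itself is exercised on
synthetic ledgers. A per-flux perturbation mode is deliberately not the
default: the published analysis used one pooled percentage per category.
Sign robustness requires every grid balance to share the centre's strict
sign; a centre of exactly zero is never robust.

## Synthetic ledger generator

The generator emulates the *shape* of farm carbon ledgers for testing:
category mix 30 % inputs / 40 % outputs / 30 % internal (roughly the 4/7/3
mix of the validation case), log-normal amounts with median ≈20 t C and
log-sd 1 (a few dominant fluxes over many small ones), variation
half-ranges uniform on 5–20 % (the band farm records typically support),
and fossil flags only on fossil-plausible pathways (external source or air
sink, 10 % chance). It does not emulate real correlation structure —
paired pass-throughs, mass closure between sites, seasonal structure — so
passing property tests demonstrates the accounting invariants (validity by
construction, conservation, internal-flux cancellation), not realism of
any particular farm. Determinism: one `numpy` generator seeded per call.

## Numerical and formatting choices

Internal arithmetic is double precision throughout; nothing is rounded
until rendering. Reports print totals to 1 decimal and per-FU rates to
2 decimals (3 when the magnitude is below 0.01, matching entries like
−0.003), as in the source layout. Ledger CSV serialisation uses the
shortest round-tripping float representation, so read(write(L)) = L
field-for-field. The ±10 % validation-case problem size is 14 fluxes; the
conservation sweep in the acceptance script uses 1000 ledgers of 12 fluxes.

## Limitations

The balance is a mass accounting, not an impact assessment: identical
masses of different materials are indistinguishable, there is no
CO2-equivalent/GWP weighting (only the CO2e→C unit conversion), no
nitrogen or water ledger, no IPCC tier emission-factor library, and no
climate/soil/management forecasting. Multi-year series are separate
ledgers. The storage convention above is a reconstruction and should be
re-validated before being applied to systems with flux structures very
different from the beef-consortium case.
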