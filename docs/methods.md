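# Methods

## Accounting model

The package estimates disposal-stage greenhouse-gas emissions for the
single-use materials consumed by IV antimicrobial therapy. It deliberately
covers only waste the hospital itself discards: drug manufacturing, shipping,
personal protective equipment, refrigeration, and emissions from
antimicrobial complications are out of scope, so totals are underestimates of
the full life-cycle footprint.

The unit operation is a mass-times-factor product. Each inventory item
carries a single EPA WARM material class — for multi-component objects, the
class of the most substantial component, assigned at data-entry time; items
that fit no specific class are entered as `mixed`. The loader validates
material names against the active factor table but never reclassifies, and a
factor lookup that fails raises an error naming the (material, method) pair
rather than silently falling back to `mixed`.

Emission factors follow the EPA GHG Emission Factors Hub convention: metric
tons CO2e per **short ton** (907 184.74 g) of material, by disposal method
(`landfilled`, `recycled`, `combusted`; `incinerated` is accepted as an input
spelling for combusted). All internal arithmetic is in metric tons CO2e;
conversion to short tons happens once, at report time. The packaged table was
transcribed from the Hub's waste table (WARM-derived, 2025 edition; the
provenance string in the CSV records this and is carried into every report
header, since Hub values change between vintages). Negative factors are
accepted — recycling pathways can carry net credits — and a net-negative
report total triggers a logged warning rather than an error.

## Aggregation conventions

* **Cross-site weights.** Items weighed at several institutions use the
  arithmetic mean of the site weighings (over the sites that measured the
  item, if coverage is partial). Weights are recorded to centigram precision,
  matching a tabletop pharmacy scale. The symmetric concordance statistic
  `|a-b| / mean(a,b)` is provided for weight-agreement summaries; the mean
  denominator is a documented choice.
* **Fractional allocations.** Boxed items contribute `1/items_per_box` per
  dose; preparations yielding several doses contribute
  `1/doses_per_preparation`. Full double precision is kept everywhere;
  two-decimal values (0.08, 0.33) are display formatting only.
* **Dose vs day of therapy.** A dose covers packaging + preparation.
  Administration materials (tubing, flushes) accrue per day of therapy, not
  per dose; per-DOT emissions are `dose x doses_per_day + admin_daily`. A
  non-default `admin_per_dose=True` flag exists for institutions that replace
  administration materials with every dose.
* **Layered averaging.** Mean item masses feed site-specific BOM counts;
  per-product totals are computed per site and then averaged across sites
  (`average_sites`, isolated behind one function so the layering can be
  switched). Agent-level (DOT calculator) and agent-and-strength-level (dose
  calculator) factors are unweighted means over the matching drug products —
  utilization-weighted averaging is deliberately not offered.
* **doses_per_day** is a real number so every-48-hour regimens enter as 0.5.

## Calculators and reports

Usage records are matched after normalization: trim, casefold, separator
unification (`piperacillin/tazobactam` ≡ `piperacillin-tazobactam`), and a
packaged synonym table for salt suffixes and brand names. An unmatched name
is reported with near-miss candidates, never guessed. Report rows keep zero
quantities (a stewardship team sees its whole agent list), are sorted by key
before summation so floating-point totals are bit-stable across platforms,
and carry CO2e in both short and metric tons (the factor base is metric; the
spreadsheet convention this mirrors labels the column short tons — both are
emitted so neither reading is lost). Equivalency columns divide total mtCO2e
by per-unit factors from the EPA GHG Equivalencies Calculator; the packaged
default set {miles driven (3.94e-4 mtCO2e/mile), gallons of gasoline
(8.887e-3), smartphones charged (8.22e-6), tree seedlings grown 10 years
(0.060)} is fully replaceable via `equivalencies.csv`. Reports serialize to
CSV (full-precision `repr` columns plus 2-decimal display companions,
metadata as `#` header lines, no timestamp by default so outputs are
reproducible byte-for-byte) or lossless JSON.

## Synthetic data

`FixtureSpec`/`generate_fixture` emulate a two-site measurement campaign: one
explicit seeded generator (no global randomness), per-site weights jittered
uniformly within ±10 % of a base mass (published between-site weight
differences were mostly under 15 %), roughly a quarter of products premixed,
every product's BOM containing exactly one drug container plus a box
allocation from {1/6, 1/10, 1/12, 1/24}, compounded vials shared across 1–3
doses, and dosing frequencies from 0.5 to 6 per day. Identical spec + seed
yields byte-identical directories. Because products are parameterized as a
constant count per agent, the generator cannot produce the published 110
products over 47 agents exactly; the dedicated synthetic supplementary writer
(below) carries that composition instead.

What the generator does **not** emulate: correlated masses within a product
family, site-specific formulary gaps, renal dosing adjustments, loading or
prophylaxis doses, and agent-specific administration setups (administration
counts are keyed by site only). Passing tests therefore demonstrate the
arithmetic and its invariants, not the realism of any particular hospital's
inventory.

`import_supplementary` maps user-supplied delimited exports of a published
per-product measurement workbook onto the inventory schema (tables recognized
by headers: products need `agent, dose_label, formulation, doses_per_day,
container_material` + `mass_g_<site>` columns; materials need `name, role,
material` + `mass_g_<site>`; optional per-dose counts), recomputes per-product
emissions, and lists discrepancies against any stated values. The workbook
itself is not redistributable, so tests run the importer on a synthetic
stand-in export (files marked `synthetic`) with the published composition:
110 products (26 premix), 47 agents, 102 inactive materials, 2 sites.

## Numerical choices and edge cases

* 1 short ton = 907 184.74 g and 1 metric ton = 1 000 000 g exactly;
  identity conversions return their input bitwise; round-trips hold to 1e-9
  relative.
* Zero mass or zero BOM count contributes exactly zero; waste-mass columns
  are independent of the disposal scenario by construction.
* Duplicate factor keys, dangling BOM references, non-numeric cells, and
  admin rows pointing at non-administration items are hard errors with row
  numbers; an empty factor file is a valid (empty) table whose lookups fail.
* The engine is verified against an independent naive triple-loop reference
  implementation to 1e-12 relative on hundreds of random small campaigns
  (≤ 4 products, ≤ 10 items, ≤ 3 sites — sizes chosen to keep the default
  suite fast while covering 1-, 2-, and 3-site averaging).

## Known limitations

* The DOT calculator assumes standard dosing with normal renal function; it
  overestimates for renally dosed patients and ignores loading/prophylaxis
  single doses (the dose and product calculators accommodate more granular
  data).
* Emission factors are disposal-stage only and vintage-dependent; users
  should pin and record their Hub vintage.
* Between-site weight concordance statistics depend on the chosen
  mean-of-measurements denominator and may not reproduce summaries computed
  with a different convention.
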