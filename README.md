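# abx-carbon

Greenhouse-gas accounting for the single-use waste behind intravenous
antimicrobial therapy.

Every IV antimicrobial dose consumes disposable packaging (paperboard and
corrugated boxes, overwraps), preparation materials (vials, diluent bags,
syringes), and administration supplies (tubing sets, flushes). When that waste
is landfilled, recycled, or combusted it releases greenhouse gases.
`abx-carbon` turns an institutional inventory of weighed items and
antimicrobial utilization data into CO2-equivalent emission estimates, so an
antimicrobial stewardship program can report avoided emissions from
interventions such as IV-to-PO conversion alongside the usual cost and
days-of-therapy metrics.

## The model

For an item of mass *m* grams with EPA WARM material class *c* disposed by
method *d* (landfilled by default):

```
E_item = (m / 907184.74) * EF(c, d)        [metric tons CO2e]
```

where `EF(c, d)` is the EPA GHG Emission Factors Hub waste factor in metric
tons CO2e per short ton. Per-dose emissions sum the bill of materials (BOM)
with fractional counts — a carton of 12 premixes charges 1/12 ≈ 0.08 boxes to
each dose, a vial yielding 3 doses charges 1/3 ≈ 0.33 vials. Per
day-of-therapy (DOT):

```
E_DOT = E_dose * doses_per_day + E_admin_daily
```

Item weights measured at several sites are averaged; per-product totals are
computed per site and then averaged; per-agent factors (the DOT calculator)
and per-agent-and-strength factors (the dose calculator) are unweighted means
over the corresponding drug products. Reports express totals in short tons of
CO2e, grams of waste, and interpretive equivalencies (miles driven, gasoline
consumed, smartphones charged, tree seedlings grown).

## Worked example

The package ships a two-product cefazolin inventory measured at two sites
(`abx_carbon/data/worked_example/`): a 1 g/50 mL frozen premix and a
3 g/100 mL locally compounded product, nine single-use items in total.

```
$ abx-carbon validate --inventory src/abx_carbon/data/worked_example
ok: 9 items, 2 products, 14 BOM rows, sites siteA, siteB

$ abx-carbon compute --mode dot \
    --usage src/abx_carbon/data/worked_example/usage_dot.csv \
    --inventory src/abx_carbon/data/worked_example \
    --out report.csv
wrote report.csv: 1 rows, total 0.002351 mtCO2e, 29979.8 g waste
```

100 IV DOT of cefazolin generate about 30 kg of single-use waste and
0.0024 metric tons CO2e — the emissions of driving roughly 6 miles. The
report CSV carries full-precision columns, 2-decimal display companions, and
a `TOTAL` row that is the exact column sum.

Other entry points: `abx-carbon compute --mode dose|product` for
more granular utilization data, `abx-carbon factors list` to inspect the
packaged emission-factor table, and `abx-carbon fixture generate --seed N
--out DIR` for synthetic campaigns.

## Adapting to your institution

Everything is a delimited-text table: replace `emission_factors.csv` (your
EPA Hub vintage), `equivalencies.csv`, the inventory tables
(`items.csv`, `products.csv`, `bom.csv`, `admin_daily.csv`), and
`scenario.json` (e.g. route corrugated boxes to recycling) — see
`docs/methods.md` for schemas and conventions.
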