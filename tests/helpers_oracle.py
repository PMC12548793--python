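"""Naive triple-loop reference implementation of the emissions accounting.

Deliberately independent of the engine module: its own unit constant, its own
loops over the raw bundle tables, no shared helper calls. Used as the oracle in
equivalence tests.
"""

GRAMS_PER_SHORT_TON = 907184.74


def _factor_for(factor_table, scenario, material):
    method = scenario.overrides.get(material, scenario.default_method)
    return factor_table.entries[(material, method)]


def _mean(values):
    values = list(values)
    return sum(values) / len(values)


def naive_dose(bundle, factor_table, scenario, product_id, site):
    """(mtco2e, waste_g) for one dose at one site: packaging + preparation."""
    mtco2e = 0.0
    waste = 0.0
    for entry in bundle.bom:
        if entry.product_id != product_id or entry.site != site:
            continue
        item = bundle.items[entry.item_id]
        mass = _mean(item.site_masses.values())
        f = _factor_for(factor_table, scenario, item.material)
        mtco2e += entry.count_per_dose * mass / GRAMS_PER_SHORT_TON * f
        waste += entry.count_per_dose * mass
    return mtco2e, waste


def naive_admin_daily(bundle, factor_table, scenario, site):
    mtco2e = 0.0
    waste = 0.0
    for item_id, count in bundle.admin_daily[site].entries.items():
        item = bundle.items[item_id]
        mass = _mean(item.site_masses.values())
        f = _factor_for(factor_table, scenario, item.material)
        mtco2e += count * mass / GRAMS_PER_SHORT_TON * f
        waste += count * mass
    return mtco2e, waste


def naive_dot(bundle, factor_table, scenario, product_id):
    """(mtco2e, waste_g) per DOT averaged over the product's sites."""
    product = bundle.products[product_id]
    sites = sorted({e.site for e in bundle.bom if e.product_id == product_id})
    per_site = []
    for site in sites:
        d_m, d_w = naive_dose(bundle, factor_table, scenario, product_id, site)
        a_m, a_w = naive_admin_daily(bundle, factor_table, scenario, site)
        per_site.append((d_m * product.doses_per_day + a_m,
                         d_w * product.doses_per_day + a_w))
    return (_mean(m for m, _ in per_site), _mean(w for _, w in per_site))


def naive_agent_factors(bundle, factor_table, scenario):
    """agent -> (mtco2e/DOT, waste_g/DOT): unweighted mean over products."""
    by_agent = {}
    for pid, product in bundle.products.items():
        by_agent.setdefault(product.agent, []).append(
            naive_dot(bundle, factor_table, scenario, pid))
    return {
        agent: (_mean(m for m, _ in results), _mean(w for _, w in results))
        for agent, results in by_agent.items()
    }
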