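"""Emissions arithmetic: item -> dose -> day-of-therapy, with cross-site and
agent-category averaging.

The accounting chain mirrors how IV antimicrobial waste accrues in practice:

* an *item* emits ``mass_short_tons x factor(material, disposal)`` mtCO2e when
  disposed;
* a *dose* emits the BOM-weighted sum over its packaging and preparation items;
* a *day of therapy* (DOT) emits ``dose x doses_per_day`` plus the
  administration materials consumed per day (tubing, flushes), which are
  charged per day rather than per dose by default;
* per-product results are computed per site and then averaged across sites;
* per-agent factors are the unweighted mean over the agent's drug products.

All arithmetic is double precision; two-decimal displays are report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataValidationError
from .inventory import DrugProduct, InventoryBundle, InventoryItem
from .reference_data import (
    DisposalScenario,
    EmissionFactorTable,
    MassUnit,
    convert_mass,
    get_factor,
)

__all__ = [
    "EmissionResult",
    "AgentFactor",
    "AgentDoseFactor",
    "item_emissions",
    "dose_emissions",
    "average_sites",
    "dot_emissions",
    "product_dose_result",
    "agent_factors",
    "agent_dose_factors",
]


@dataclass
class EmissionResult:
    """Emissions (metric tons CO2e) and waste mass (grams) for one accounting unit.

    When per-site components are retained in ``site_values`` the headline values
    are their arithmetic means.
    """

    mtco2e: float
    waste_mass_g: float
    site_values: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if self.waste_mass_g < 0:
            raise DataValidationError(f"waste mass cannot be negative: {self.waste_mass_g}")


@dataclass(frozen=True)
class AgentFactor:
    """Per-DOT emission factor for one agent (mean over its drug products)."""

    agent: str
    mtco2e_per_dot: float
    waste_g_per_dot: float
    n_products_averaged: int


@dataclass(frozen=True)
class AgentDoseFactor:
    """Per-dose emission factor for one (agent, dose strength) category."""

    agent: str
    dose_label: str
    mtco2e_per_dose: float
    waste_g_per_dose: float
    n_products_averaged: int


def item_emissions(
    item: InventoryItem,
    mass_g: float,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
) -> float:
    """mtCO2e from disposing ``mass_g`` grams of the item's material."""
    if mass_g < 0:
        raise DataValidationError(f"item {item.item_id!r}: mass cannot be negative")
    if mass_g == 0:
        return 0.0
    factor = get_factor(factors, item.material, scenario)
    return convert_mass(mass_g, MassUnit.GRAM, MassUnit.SHORT_TON) * factor


def dose_emissions(
    product: DrugProduct,
    site: str,
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
) -> EmissionResult:
    """Packaging + preparation emissions for one dose of a product at one site.

    Counts are the site's per-dose BOM; masses are cross-site mean item masses.
    Administration materials are *not* part of a dose — they accrue per day.
    """
    entries = inventory.bom_for(product.product_id, site)
    if not entries:
        raise DataValidationError(
            f"product {product.product_id!r} has no BOM at site {site!r}"
        )
    mtco2e = 0.0
    waste_g = 0.0
    for entry in entries:
        item = inventory.items[entry.item_id]
        mean_mass = item.mean_mass
        mtco2e += entry.count_per_dose * item_emissions(item, mean_mass, factors, scenario)
        waste_g += entry.count_per_dose * mean_mass
    return EmissionResult(mtco2e=mtco2e, waste_mass_g=waste_g)


def admin_daily_emissions(
    site: str,
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
) -> EmissionResult:
    """Emissions from administration materials consumed per day at one site."""
    if site not in inventory.admin_daily:
        raise DataValidationError(f"no administration daily BOM for site {site!r}")
    mtco2e = 0.0
    waste_g = 0.0
    for item_id, count in inventory.admin_daily[site].entries.items():
        item = inventory.items[item_id]
        mean_mass = item.mean_mass
        mtco2e += count * item_emissions(item, mean_mass, factors, scenario)
        waste_g += count * mean_mass
    return EmissionResult(mtco2e=mtco2e, waste_mass_g=waste_g)


def average_sites(results: dict[str, EmissionResult]) -> EmissionResult:
    """Arithmetic mean over sites, retaining the per-site components."""
    if not results:
        raise DataValidationError("cannot average an empty site->result map")
    n = len(results)
    return EmissionResult(
        mtco2e=sum(r.mtco2e for r in results.values()) / n,
        waste_mass_g=sum(r.waste_mass_g for r in results.values()) / n,
        site_values={s: (r.mtco2e, r.waste_mass_g) for s, r in sorted(results.items())},
    )


def dot_emissions(
    product: DrugProduct,
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
    admin_per_dose: bool = False,
) -> EmissionResult:
    """Per-DOT emissions for a product: site-wise dose x doses/day + daily admin,
    then averaged across the sites that carry the product.

    ``admin_per_dose=True`` switches the administration term to accrue with every
    dose instead of once per day (non-default; some institutions re-prime lines
    per dose).
    """
    sites = inventory.bom_sites(product.product_id)
    if not sites:
        raise DataValidationError(f"product {product.product_id!r} has no BOM at any site")
    per_site: dict[str, EmissionResult] = {}
    for site in sites:
        dose = dose_emissions(product, site, inventory, factors, scenario)
        admin = admin_daily_emissions(site, inventory, factors, scenario)
        admin_scale = product.doses_per_day if admin_per_dose else 1.0
        per_site[site] = EmissionResult(
            mtco2e=dose.mtco2e * product.doses_per_day + admin.mtco2e * admin_scale,
            waste_mass_g=dose.waste_mass_g * product.doses_per_day
            + admin.waste_mass_g * admin_scale,
        )
    return average_sites(per_site)


def product_dose_result(
    product: DrugProduct,
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
) -> EmissionResult:
    """Per-dose emissions for a product averaged across its sites."""
    sites = inventory.bom_sites(product.product_id)
    if not sites:
        raise DataValidationError(f"product {product.product_id!r} has no BOM at any site")
    return average_sites(
        {s: dose_emissions(product, s, inventory, factors, scenario) for s in sites}
    )


def agent_factors(
    products: dict[str, DrugProduct],
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
    admin_per_dose: bool = False,
) -> list[AgentFactor]:
    """Per-DOT factors averaged (unweighted) within each agent category."""
    by_agent: dict[str, list[EmissionResult]] = {}
    for pid in sorted(products):
        product = products[pid]
        result = dot_emissions(product, inventory, factors, scenario,
                               admin_per_dose=admin_per_dose)
        by_agent.setdefault(product.agent, []).append(result)
    out = []
    for agent in sorted(by_agent):
        results = by_agent[agent]
        n = len(results)
        out.append(AgentFactor(
            agent=agent,
            mtco2e_per_dot=sum(r.mtco2e for r in results) / n,
            waste_g_per_dot=sum(r.waste_mass_g for r in results) / n,
            n_products_averaged=n,
        ))
    return out


def agent_dose_factors(
    products: dict[str, DrugProduct],
    inventory: InventoryBundle,
    factors: EmissionFactorTable,
    scenario: DisposalScenario,
) -> list[AgentDoseFactor]:
    """Per-dose factors averaged within (agent, dose strength) categories.

    Formulation variants of the same strength (e.g. frozen premix vs locally
    compounded) fall in one category and are averaged unweighted.
    """
    by_key: dict[tuple[str, str], list[EmissionResult]] = {}
    for pid in sorted(products):
        product = products[pid]
        result = product_dose_result(product, inventory, factors, scenario)
        by_key.setdefault((product.agent, product.dose_label), []).append(result)
    out = []
    for agent, dose_label in sorted(by_key):
        results = by_key[(agent, dose_label)]
        n = len(results)
        out.append(AgentDoseFactor(
            agent=agent,
            dose_label=dose_label,
            mtco2e_per_dose=sum(r.mtco2e for r in results) / n,
            waste_g_per_dose=sum(r.waste_mass_g for r in results) / n,
            n_products_averaged=n,
        ))
    return out
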