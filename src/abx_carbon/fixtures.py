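"""Seeded synthetic inventories and usage tables, plus a supplementary importer.

The generator emulates the structure of a two-site hospital measurement
campaign: a formulary of IV antimicrobial agents, each with one or more drug
products (frozen/nonfrozen premixes vs locally compounded or Mini-Bag Plus
admixtures), per-site item weighings jittered around a common base mass,
fractional box allocations, shared-vial allocations, and per-day administration
materials. Everything is driven by one explicit seeded generator; identical
spec + seed produces byte-identical files.

``import_supplementary`` maps a user-supplied delimited-text export of a
published per-product measurement workbook onto the inventory schema and
cross-checks recomputed emissions against any stated per-dose values.
``write_synthetic_supplementary`` emits a synthetic stand-in export with the
same layout for tests that must run without the real workbook.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import product_dose_result
from .errors import DataValidationError, SchemaError
from .inventory import (
    FormulationType,
    InventoryBundle,
    ItemRole,
    load_inventory,
    write_inventory,
)
from .reference_data import (
    DisposalScenario,
    EmissionFactorTable,
    packaged_emission_factors,
)

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "load_fixture",
    "ImportResult",
    "import_supplementary",
    "write_synthetic_supplementary",
]

#: fractional box allocations observed in practice (items shipped per box)
BOX_ALLOCATIONS = (1 / 6, 1 / 10, 1 / 12, 1 / 24)

_AGENT_POOL = [
    "vancomycin", "cefazolin", "ceftriaxone", "cefepime", "ceftazidime",
    "piperacillin-tazobactam", "ampicillin", "ampicillin-sulbactam", "nafcillin",
    "oxacillin", "penicillin g", "meropenem", "ertapenem", "imipenem-cilastatin",
    "aztreonam", "ciprofloxacin", "levofloxacin", "moxifloxacin", "azithromycin",
    "erythromycin", "clindamycin", "metronidazole", "doxycycline", "tigecycline",
    "gentamicin", "tobramycin", "amikacin", "daptomycin", "linezolid",
    "tedizolid", "ceftaroline", "ceftolozane-tazobactam", "ceftazidime-avibactam",
    "meropenem-vaborbactam", "trimethoprim-sulfamethoxazole", "rifampin",
    "acyclovir", "ganciclovir", "foscarnet", "remdesivir", "fluconazole",
    "voriconazole", "posaconazole", "isavuconazole", "micafungin", "caspofungin",
    "amphotericin b", "colistin", "polymyxin b", "dalbavancin",
]

_DOSE_LABELS = ["250 mg/50 mL", "500 mg/50 mL", "1 g/50 mL", "1.5 g/100 mL",
                "2 g/100 mL", "3 g/100 mL", "4 g/250 mL"]

_PREP_ITEM_NAMES = [
    "60 mL syringe", "vial adapter", "sterile water 50 mL bag", "diluent bag 100 mL",
    "transfer needle", "compounding tubing set", "alcohol prep pad", "filter needle",
    "label sheet", "sterile cap", "pharmacy overwrap bag", "dispensing pin",
]

_ADMIN_ITEM_NAMES = [
    "primary IV tubing set", "secondary IV tubing set", "saline flush syringe",
    "extension set", "end cap", "IV pump cassette",
]

_PREP_MATERIALS = ["polypropylene", "mixed plastics", "pet", "hdpe", "ldpe", "mixed"]
_ADMIN_MATERIALS = ["polypropylene", "mixed plastics", "pvc"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic campaign.

    Defaults mirror a two-site academic-hospital audit: weights jittered within
    +/-10 percent between sites (most published between-site weight differences
    were under 15 percent), roughly a quarter of products premixed, and dosing
    frequencies from every-48-hours (0.5/day) to every-4-hours (6/day).
    """

    seed: int = 0
    n_agents: int = 6
    n_products_per_agent: int = 2
    n_items: int = 24
    n_sites: int = 2
    mass_range_g: tuple[float, float] = (0.5, 120.0)
    material_pool: list[str] = field(default_factory=lambda: list(_PREP_MATERIALS))
    doses_per_day_pool: list[float] = field(default_factory=lambda: [0.5, 1, 2, 3, 4, 6])
    premix_fraction: float = 26 / 110

    def __post_init__(self):
        for name in ("n_agents", "n_products_per_agent", "n_items", "n_sites"):
            if getattr(self, name) < 1:
                raise DataValidationError(f"{name} must be a positive integer")
        lo, hi = self.mass_range_g
        if not (0 < lo <= hi):
            raise DataValidationError(f"mass_range_g must be 0 < low <= high, got {self.mass_range_g}")
        if not self.material_pool or not self.doses_per_day_pool:
            raise DataValidationError("material and doses-per-day pools must be non-empty")
        if not 0 <= self.premix_fraction <= 1:
            raise DataValidationError(
                f"premix_fraction must lie in [0, 1], got {self.premix_fraction} "
                "(cannot have more premix products than products)"
            )
        if self.n_products_per_agent > len(_DOSE_LABELS):
            raise DataValidationError(
                f"n_products_per_agent > {len(_DOSE_LABELS)} would force duplicate "
                "(agent, dose_label, formulation) keys"
            )

    @property
    def n_products(self) -> int:
        return self.n_agents * self.n_products_per_agent


def _site_ids(n_sites: int) -> list[str]:
    return [f"site{chr(ord('A') + i)}" for i in range(n_sites)]


def _jittered_masses(rng, base: float, n_sites: int) -> dict[str, float]:
    """Per-site weighings: +/-10% around the base mass, centigram precision."""
    out = {}
    for site in _site_ids(n_sites):
        mass = round(float(base) * float(rng.uniform(0.9, 1.1)), 2)
        out[site] = max(mass, 0.01)
    return out


def generate_fixture(spec: FixtureSpec, out_dir) -> InventoryBundle:
    """Write a complete synthetic inventory + usage directory; return the bundle.

    Every product's BOM contains exactly one drug-container item plus a
    fractional box allocation from {1/6, 1/10, 1/12, 1/24}; compounded products
    additionally share vials across doses (1, 1/2, or 1/3 vial per dose) and
    consume 1-3 preparation items.
    """
    n_fixed_packaging = 2  # shared premix corrugated box + vial paperboard box
    n_admin = max(2, min(len(_ADMIN_ITEM_NAMES), round(0.1 * spec.n_items)))
    n_prep = spec.n_items - spec.n_products - n_fixed_packaging - n_admin
    if n_prep < 1:
        raise DataValidationError(
            f"impossible spec: n_items={spec.n_items} cannot hold "
            f"{spec.n_products} container items, {n_fixed_packaging} packaging "
            f"items, {n_admin} administration items, and >=1 preparation item"
        )
    if spec.n_agents > len(_AGENT_POOL):
        raise DataValidationError(f"n_agents must be <= {len(_AGENT_POOL)}")

    rng = np.random.default_rng(spec.seed)
    sites = _site_ids(spec.n_sites)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    agents = _AGENT_POOL[: spec.n_agents]
    n_premix = int(round(spec.premix_fraction * spec.n_products))
    premix_flags = np.zeros(spec.n_products, dtype=bool)
    premix_flags[rng.permutation(spec.n_products)[:n_premix]] = True

    lo, hi = spec.mass_range_g
    item_rows = []       # item_id -> (name, role, material, site_masses)
    products = []
    bom_rows = []

    # shared packaging items
    box_premix = ("BOX-PREMIX", "premix corrugated box", ItemRole.DRUG_PACKAGING,
                  "corrugated containers", _jittered_masses(rng, rng.uniform(30, 90), spec.n_sites))
    box_vial = ("BOX-VIAL", "vial paperboard box", ItemRole.DRUG_PACKAGING,
                "mixed paper (general)", _jittered_masses(rng, rng.uniform(5, 25), spec.n_sites))
    item_rows += [box_premix, box_vial]

    prep_items = []
    for j in range(n_prep):
        name = _PREP_ITEM_NAMES[j % len(_PREP_ITEM_NAMES)]
        material = spec.material_pool[int(rng.integers(len(spec.material_pool)))]
        iid = f"PREP-{j + 1:03d}"
        item_rows.append((iid, name, ItemRole.PREPARATION, material,
                          _jittered_masses(rng, rng.uniform(lo, hi), spec.n_sites)))
        prep_items.append(iid)

    admin_items = []
    for j in range(n_admin):
        name = _ADMIN_ITEM_NAMES[j % len(_ADMIN_ITEM_NAMES)]
        material = _ADMIN_MATERIALS[int(rng.integers(len(_ADMIN_MATERIALS)))]
        iid = f"ADM-{j + 1:03d}"
        item_rows.append((iid, name, ItemRole.ADMINISTRATION, material,
                          _jittered_masses(rng, rng.uniform(lo, hi), spec.n_sites)))
        admin_items.append(iid)

    k = 0
    for agent in agents:
        dose_order = rng.permutation(len(_DOSE_LABELS))[: spec.n_products_per_agent]
        for slot in range(spec.n_products_per_agent):
            pid = f"P{k + 1:04d}"
            dose_label = _DOSE_LABELS[int(dose_order[slot])]
            is_premix = bool(premix_flags[k])
            if is_premix:
                formulation = (FormulationType.FROZEN_PREMIX if rng.uniform() < 0.5
                               else FormulationType.NONFROZEN_PREMIX)
                container = (f"CONT-{pid}", f"{agent} {dose_label} premix bag",
                             ItemRole.DRUG_CONTAINER, "mixed plastics",
                             _jittered_masses(rng, rng.uniform(20, 80), spec.n_sites))
                container_count, box_id = 1.0, "BOX-PREMIX"
            else:
                formulation = (FormulationType.MINIBAG_PLUS if rng.uniform() < 0.3
                               else FormulationType.LOCAL_COMPOUND)
                container = (f"CONT-{pid}", f"{agent} {dose_label} vial",
                             ItemRole.DRUG_CONTAINER, "glass",
                             _jittered_masses(rng, rng.uniform(10, 60), spec.n_sites))
                # shared preparations: 1, 2, or 3 doses drawn from one vial
                container_count = 1.0 / int(rng.integers(1, 4))
                box_id = "BOX-VIAL"
            item_rows.append(container)
            doses_per_day = float(spec.doses_per_day_pool[
                int(rng.integers(len(spec.doses_per_day_pool)))])
            products.append((pid, agent, dose_label, formulation, doses_per_day))

            box_count = BOX_ALLOCATIONS[int(rng.integers(len(BOX_ALLOCATIONS)))]
            chosen_prep = [prep_items[int(i)] for i in
                           rng.permutation(len(prep_items))[: int(rng.integers(1, 4))]]
            for site_i, site in enumerate(sites):
                bom_rows.append((pid, container[0], site, container_count))
                bom_rows.append((pid, box_id, site, box_count))
                for prep_iid in chosen_prep:
                    count = float(int(rng.integers(1, 3)))
                    # sites occasionally tally one extra consumable
                    if site_i > 0 and rng.uniform() < 0.2:
                        count += 1.0
                    bom_rows.append((pid, prep_iid, site, count))
            k += 1

    admin_daily_rows = []
    for site in sites:
        for iid in admin_items:
            admin_daily_rows.append((site, iid, float([1, 1, 2, 4][int(rng.integers(4))])))

    # ---- write files (canonical, deterministic) ----
    def w(name: str, header: str, rows: list[str]) -> None:
        (out / name).write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")

    w("items.csv", "item_id,name,role,material,site,mass_g",
      [f"{iid},{name},{role.value},{material},{site},{mass!r}"
       for iid, name, role, material, masses in sorted(item_rows)
       for site, mass in sorted(masses.items())])
    w("products.csv", "product_id,agent,dose_label,formulation,doses_per_day",
      [f"{pid},{agent},{label},{form.value},{dpd!r}"
       for pid, agent, label, form, dpd in sorted(products)])
    w("bom.csv", "product_id,item_id,site,count_per_dose",
      [f"{pid},{iid},{site},{count!r}"
       for pid, iid, site, count in sorted(bom_rows)])
    w("admin_daily.csv", "site,item_id,count_per_day",
      [f"{site},{iid},{count!r}" for site, iid, count in sorted(admin_daily_rows)])

    w("usage_dot.csv", "agent,iv_dot",
      [f"{agent},{int(rng.integers(50, 1000))}" for agent in agents])
    dose_keys = sorted({(agent, label) for _, agent, label, _, _ in products})
    w("usage_dose.csv", "agent,dose_label,n_doses",
      [f"{agent},{label},{int(rng.integers(20, 500))}" for agent, label in dose_keys])
    w("usage_product.csv", "product_id,n_doses",
      [f"{pid},{int(rng.integers(20, 500))}" for pid, *_ in sorted(products)])
    (out / "scenario.json").write_text(
        json.dumps({"default_method": "landfilled", "overrides": {}}, indent=2) + "\n",
        encoding="utf-8")

    return load_fixture(out)


def load_fixture(fixture_dir, factor_table: EmissionFactorTable | None = None) -> InventoryBundle:
    """Load a fixture directory written by :func:`generate_fixture`."""
    d = Path(fixture_dir)
    return load_inventory(d / "items.csv", d / "products.csv", d / "bom.csv",
                          d / "admin_daily.csv", factor_table=factor_table)


# ---------------------------------------------------------------------------
# supplementary importer


@dataclass
class ImportResult:
    bundle: InventoryBundle
    n_products: int
    n_inactive_materials: int
    #: (product_id, recomputed mtCO2e/dose, stated mtCO2e/dose) where they differ
    discrepancies: list[tuple[str, float, float]]


_PRODUCT_REQUIRED = {"agent", "dose_label", "formulation", "doses_per_day",
                     "container_material"}
_MATERIAL_REQUIRED = {"name", "role", "material"}
_COUNT_REQUIRED = {"product_id", "item_id", "site", "count_per_dose"}


def _mass_columns(columns) -> dict[str, str]:
    """Map 'mass_g_<site>' columns to site ids."""
    out = {}
    for c in columns:
        if c.startswith("mass_g_"):
            out[c] = c[len("mass_g_"):]
    return out


def import_supplementary(
    paths,
    scenario: DisposalScenario | None = None,
    factor_table: EmissionFactorTable | None = None,
    rel_tol: float = 1e-6,
) -> ImportResult:
    """Map delimited-text exports of a per-product measurement workbook onto the
    inventory schema.

    Expects among ``paths``: a drug-products table (columns ``agent, dose_label,
    formulation, doses_per_day, container_material`` plus per-site
    ``mass_g_<site>`` weights and optionally ``stated_mtco2e_per_dose``), an
    inactive-materials table (``name, role, material`` plus ``mass_g_<site>``),
    and optionally a per-dose counts table (``product_id, item_id, site,
    count_per_dose``). Tables are recognized by their headers; an unrecognized
    layout raises a schema error listing the headers found. Per-product per-dose
    emissions are recomputed and compared against any stated values.
    """
    if scenario is None:
        scenario = DisposalScenario()
    if factor_table is None:
        factor_table = packaged_emission_factors()

    products_df = materials_df = counts_df = None
    seen_headers = []
    for p in map(Path, paths):
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        cols = set(df.columns)
        seen_headers.append((p.name, sorted(cols)))
        if _PRODUCT_REQUIRED <= cols:
            products_df = df
        elif _COUNT_REQUIRED <= cols:
            counts_df = df
        elif _MATERIAL_REQUIRED <= cols:
            materials_df = df
    if products_df is None or materials_df is None:
        raise SchemaError(
            "could not recognize the supplementary layout; need a products table "
            f"with columns {sorted(_PRODUCT_REQUIRED)} and a materials table with "
            f"columns {sorted(_MATERIAL_REQUIRED)} (each plus mass_g_<site> "
            f"weight columns); detected headers: {seen_headers}"
        )

    item_lines = ["item_id,name,role,material,site,mass_g"]
    product_lines = ["product_id,agent,dose_label,formulation,doses_per_day"]
    bom_lines = ["product_id,item_id,site,count_per_dose"]
    admin_lines = ["site,item_id,count_per_day"]

    pmass = _mass_columns(products_df.columns)
    if not pmass:
        raise SchemaError("products table has no mass_g_<site> weight columns")
    stated: dict[str, float] = {}
    sites_seen: set[str] = set()
    for i, row in enumerate(products_df.itertuples(index=False), start=1):
        pid = getattr(row, "product_id", "") or f"SP{i:04d}"
        product_lines.append(
            f"{pid},{row.agent},{row.dose_label},{row.formulation},{row.doses_per_day}")
        cid = f"CONT-{pid}"
        for col, site in pmass.items():
            value = getattr(row, col)
            if value == "":
                continue
            item_lines.append(
                f"{cid},{row.agent} {row.dose_label} container,drug_container,"
                f"{row.container_material},{site},{value}")
            bom_lines.append(f"{pid},{cid},{site},1.0")
            sites_seen.add(site)
        if "stated_mtco2e_per_dose" in products_df.columns:
            raw = getattr(row, "stated_mtco2e_per_dose")
            if raw != "":
                stated[pid] = float(raw)

    mmass = _mass_columns(materials_df.columns)
    if not mmass:
        raise SchemaError("materials table has no mass_g_<site> weight columns")
    n_inactive = 0
    for i, row in enumerate(materials_df.itertuples(index=False), start=1):
        iid = getattr(row, "item_id", "") or f"SM{i:04d}"
        n_inactive += 1
        role = row.role.strip().lower()
        for col, site in mmass.items():
            value = getattr(row, col)
            if value == "":
                continue
            item_lines.append(f"{iid},{row.name},{role},{row.material},{site},{value}")
            sites_seen.add(site)
            if role == "administration":
                count = getattr(row, "count_per_day", "") or "1.0"
                admin_lines.append(f"{site},{iid},{count}")

    if counts_df is not None:
        for row in counts_df.itertuples(index=False):
            bom_lines.append(
                f"{row.product_id},{row.item_id},{row.site},{row.count_per_dose}")

    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "items.csv").write_text("\n".join(item_lines) + "\n", encoding="utf-8")
        (tmp / "products.csv").write_text("\n".join(product_lines) + "\n", encoding="utf-8")
        (tmp / "bom.csv").write_text("\n".join(bom_lines) + "\n", encoding="utf-8")
        (tmp / "admin_daily.csv").write_text("\n".join(admin_lines) + "\n", encoding="utf-8")
        bundle = load_fixture(tmp, factor_table=factor_table)

    discrepancies = []
    for pid, stated_value in stated.items():
        recomputed = product_dose_result(bundle.products[pid], bundle,
                                         factor_table, scenario).mtco2e
        denom = max(abs(stated_value), 1e-30)
        if abs(recomputed - stated_value) / denom > rel_tol:
            discrepancies.append((pid, recomputed, stated_value))

    return ImportResult(bundle=bundle, n_products=len(bundle.products),
                        n_inactive_materials=n_inactive, discrepancies=discrepancies)


def write_synthetic_supplementary(
    out_dir,
    seed: int = 0,
    n_agents: int = 47,
    n_products: int = 110,
    n_premix: int = 26,
    n_inactive_materials: int = 102,
    n_sites: int = 2,
) -> list[Path]:
    """SYNTHETIC stand-in for a published supplementary measurement export.

    Emits the canonical importer layout with the composition of the published
    two-site campaign (47 agents; 110 drug products of which 26 are premixes;
    102 inactive preparation/administration materials; 2 sites). The masses,
    counts, and stated emissions are generated, not measured — files carry a
    ``synthetic`` name marker and exist so the import pipeline is testable
    without the real workbook.
    """
    if n_premix > n_products:
        raise DataValidationError("cannot have more premix products than products")
    if n_agents > min(n_products, len(_AGENT_POOL)):
        raise DataValidationError("n_agents must be <= n_products and the agent pool")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites = _site_ids(n_sites)
    mass_cols = ",".join(f"mass_g_{s}" for s in sites)

    # partition products over agents: every agent >= 1 product
    base, extra = divmod(n_products, n_agents)
    per_agent = [base + (1 if i < extra else 0) for i in range(n_agents)]
    premix_flags = np.zeros(n_products, dtype=bool)
    premix_flags[rng.permutation(n_products)[:n_premix]] = True

    factor_table = packaged_emission_factors()
    scenario = DisposalScenario()

    prod_lines = ["product_id,agent,dose_label,formulation,doses_per_day,"
                  "container_material," + mass_cols + ",stated_mtco2e_per_dose"]
    k = 0
    for i, agent in enumerate(_AGENT_POOL[:n_agents]):
        labels = rng.permutation(len(_DOSE_LABELS))[: per_agent[i]]
        for j in range(per_agent[i]):
            pid = f"SP{k + 1:04d}"
            label = _DOSE_LABELS[int(labels[j % len(labels)])]
            if premix_flags[k]:
                formulation = ("frozen_premix" if rng.uniform() < 0.5
                               else "nonfrozen_premix")
                material, base_mass = "mixed plastics", rng.uniform(20, 80)
            else:
                formulation = ("minibag_plus" if rng.uniform() < 0.3
                               else "local_compound")
                material, base_mass = "glass", rng.uniform(10, 60)
            dpd = [0.5, 1, 2, 3, 4, 6][int(rng.integers(6))]
            masses = _jittered_masses(rng, base_mass, n_sites)
            factor = factor_table.get(material, scenario.default_method)
            stated = (sum(masses.values()) / len(masses)) / 907_184.74 * factor
            prod_lines.append(
                f"{pid},{agent},{label},{formulation},{dpd},"
                + material + ","
                + ",".join(repr(masses[s]) for s in sites)
                + f",{stated!r}")
            k += 1

    mat_lines = ["item_id,name,role,material,count_per_day," + mass_cols]
    n_admin = 12
    for j in range(n_inactive_materials):
        role = "administration" if j < n_admin else "preparation"
        pool = _ADMIN_ITEM_NAMES if role == "administration" else _PREP_ITEM_NAMES
        name = f"{pool[j % len(pool)]} #{j + 1}"
        material = (_ADMIN_MATERIALS if role == "administration"
                    else _PREP_MATERIALS)[int(rng.integers(3))]
        masses = _jittered_masses(rng, rng.uniform(0.5, 120.0), n_sites)
        count = float([1, 1, 2, 4][int(rng.integers(4))]) if role == "administration" else ""
        mat_lines.append(f"SM{j + 1:04d},{name},{role},{material},{count},"
                         + ",".join(repr(masses[s]) for s in sites))

    p1 = out / "supplementary_products_synthetic.csv"
    p2 = out / "supplementary_materials_synthetic.csv"
    p1.write_text("\n".join(prod_lines) + "\n", encoding="utf-8")
    p2.write_text("\n".join(mat_lines) + "\n", encoding="utf-8")
    return [p1, p2]
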