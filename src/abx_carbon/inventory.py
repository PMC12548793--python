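"""Inventory model: weighable items, drug products, and bills of materials.

An inventory bundle ties together four delimited-text tables:

``items.csv``
    one row per item x site (``item_id,name,role,material,site,mass_g``); the
    loader aggregates per-site weighings into one :class:`InventoryItem` whose
    ``mean_mass`` is the cross-site arithmetic mean. Weights are recorded to
    centigram precision, mirroring a tabletop pharmacy scale.
``products.csv``
    ``product_id,agent,dose_label,formulation,doses_per_day``.
``bom.csv``
    per-dose packaging + preparation counts, ``product_id,item_id,site,count_per_dose``;
    counts may be fractional (a box of 12 premixes contributes 1/12 box per dose).
``admin_daily.csv``
    per-day administration counts keyed by site only,
    ``site,item_id,count_per_day`` (infusion tubing, flushes, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import DanglingReferenceError, DataValidationError, SchemaError
from .reference_data import EmissionFactorTable, MIXED_MATERIAL, normalize_material

__all__ = [
    "ItemRole",
    "FormulationType",
    "InventoryItem",
    "DrugProduct",
    "BomEntry",
    "AdminDailyBom",
    "InventoryBundle",
    "average_site_mass",
    "relative_difference",
    "per_dose_count_from_box",
    "per_dose_count_from_shared_prep",
    "load_inventory",
    "write_inventory",
]


class ItemRole(str, Enum):
    DRUG_PACKAGING = "drug_packaging"
    DRUG_CONTAINER = "drug_container"
    PREPARATION = "preparation"
    ADMINISTRATION = "administration"


class FormulationType(str, Enum):
    """How the IV product reaches a ready-to-infuse state."""

    LOCAL_COMPOUND = "local_compound"
    MINIBAG_PLUS = "minibag_plus"
    FROZEN_PREMIX = "frozen_premix"
    NONFROZEN_PREMIX = "nonfrozen_premix"


def average_site_mass(site_masses: dict[str, float]) -> float:
    """Arithmetic mean of per-site weighings of one item.

    A single-site measurement is returned unchanged; when several sites weighed
    the same object the measurements are averaged, absorbing manufacturer and
    scale differences between institutions.
    """
    if not site_masses:
        raise DataValidationError("cannot average an empty site->mass map")
    for site, mass in site_masses.items():
        if not (isinstance(mass, (int, float)) and math.isfinite(mass) and mass > 0):
            raise DataValidationError(f"site {site!r}: mass must be a positive finite "
                                      f"number of grams, got {mass!r}")
    return sum(site_masses.values()) / len(site_masses)


def relative_difference(a: float, b: float) -> float:
    """Symmetric relative difference |a - b| / mean(a, b) between two weighings."""
    if not (a > 0 and b > 0):
        raise DataValidationError(f"weights must be positive, got ({a}, {b})")
    return abs(a - b) / ((a + b) / 2.0)


def per_dose_count_from_box(items_per_box: int) -> float:
    """Fractional box allocated to one dose when items ship ``items_per_box`` to a box.

    A carton of 12 frozen-premix bags charges 1/12 ≈ 0.08 of the carton to each
    dose. Full precision is kept; 2-decimal rounding is report formatting only.
    """
    if not (isinstance(items_per_box, int) and items_per_box >= 1):
        raise DataValidationError(f"items_per_box must be a positive integer, got {items_per_box!r}")
    return 1.0 / items_per_box


def per_dose_count_from_shared_prep(doses_per_preparation: int) -> float:
    """Fractional item per dose when one preparation yields several doses.

    Drawing three 3 g/100 mL doses from one 10 g vial charges 1/3 ≈ 0.33 of the
    vial (and of its paperboard box share) to each dose.
    """
    if not (isinstance(doses_per_preparation, int) and doses_per_preparation >= 1):
        raise DataValidationError(
            f"doses_per_preparation must be a positive integer, got {doses_per_preparation!r}"
        )
    return 1.0 / doses_per_preparation


@dataclass
class InventoryItem:
    """A single-use object with per-site masses and a WARM material class.

    Multi-component objects carry the single material of their most substantial
    component; anything unclassifiable is entered as ``"mixed"`` at data-entry
    time — the loader validates but never reclassifies.
    """

    item_id: str
    name: str
    role: ItemRole
    material: str
    site_masses: dict[str, float]

    def __post_init__(self):
        self.role = ItemRole(self.role)
        self.material = normalize_material(self.material)
        if not self.item_id:
            raise DataValidationError("item_id must be non-empty")
        if not self.material:
            raise DataValidationError(f"item {self.item_id!r}: empty material")
        # triggers positivity/emptiness validation
        average_site_mass(self.site_masses)

    @property
    def mean_mass(self) -> float:
        """Cross-site mean mass in grams (over the sites that weighed the item)."""
        return average_site_mass(self.site_masses)

    @property
    def site_coverage(self) -> list[str]:
        return sorted(self.site_masses)


@dataclass
class DrugProduct:
    product_id: str
    agent: str
    dose_label: str
    formulation: FormulationType
    doses_per_day: float

    def __post_init__(self):
        self.formulation = FormulationType(self.formulation)
        self.agent = " ".join(str(self.agent).split()).casefold()
        self.dose_label = str(self.dose_label).strip()
        self.doses_per_day = float(self.doses_per_day)
        if not self.doses_per_day > 0:
            raise DataValidationError(
                f"product {self.product_id!r}: doses_per_day must be > 0, "
                f"got {self.doses_per_day}"
            )


@dataclass(frozen=True)
class BomEntry:
    product_id: str
    item_id: str
    site: str
    count_per_dose: float

    def __post_init__(self):
        if not (math.isfinite(self.count_per_dose) and self.count_per_dose >= 0):
            raise DataValidationError(
                f"BOM ({self.product_id}, {self.item_id}, {self.site}): "
                f"count_per_dose must be finite and >= 0, got {self.count_per_dose}"
            )


@dataclass
class AdminDailyBom:
    """Average administration-material counts consumed per day at one site."""

    site: str
    entries: dict[str, float]

    def __post_init__(self):
        for item_id, count in self.entries.items():
            if not (math.isfinite(count) and count >= 0):
                raise DataValidationError(
                    f"admin BOM site {self.site!r}, item {item_id!r}: "
                    f"count_per_day must be finite and >= 0, got {count}"
                )


@dataclass
class InventoryBundle:
    items: dict[str, InventoryItem]
    products: dict[str, DrugProduct]
    bom: list[BomEntry]
    admin_daily: dict[str, AdminDailyBom]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_products(self) -> int:
        return len(self.products)

    @property
    def sites(self) -> list[str]:
        sites = {s for item in self.items.values() for s in item.site_masses}
        sites.update(e.site for e in self.bom)
        sites.update(self.admin_daily)
        return sorted(sites)

    def bom_for(self, product_id: str, site: str) -> list[BomEntry]:
        return [e for e in self.bom if e.product_id == product_id and e.site == site]

    def bom_sites(self, product_id: str) -> list[str]:
        return sorted({e.site for e in self.bom if e.product_id == product_id})


# ---------------------------------------------------------------------------
# loading / writing

_ITEM_COLS = ["item_id", "name", "role", "material", "site", "mass_g"]
_PRODUCT_COLS = ["product_id", "agent", "dose_label", "formulation", "doses_per_day"]
_BOM_COLS = ["product_id", "item_id", "site", "count_per_dose"]
_ADMIN_COLS = ["site", "item_id", "count_per_day"]


def _read(path, cols) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _as_float(value, where: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise DataValidationError(f"{where}: non-numeric value {value!r}") from None


def load_inventory(
    items_path,
    products_path,
    bom_path,
    admin_bom_path,
    factor_table: EmissionFactorTable | None = None,
) -> InventoryBundle:
    """Load and cross-validate the four inventory tables into a bundle.

    Every BOM row must reference an existing item and product; every admin row an
    existing administration-role item. When ``factor_table`` is given, each item's
    material must be present in it (under the landfilled pathway, which the
    packaged tables carry for every material) — an unknown material is an error
    suggesting the ``"mixed"`` class rather than a silent reclassification.
    """
    items_df = _read(items_path, _ITEM_COLS)
    items: dict[str, InventoryItem] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    masses: dict[str, dict[str, float]] = {}
    for i, row in enumerate(items_df.itertuples(index=False), start=2):
        iid = row.item_id.strip()
        mass = _as_float(row.mass_g, f"items row {i}")
        key = (row.name, row.role, row.material)
        if iid in meta and meta[iid] != key:
            raise DataValidationError(
                f"items row {i}: item {iid!r} re-declared with conflicting "
                f"name/role/material {key} != {meta[iid]}"
            )
        meta[iid] = key
        site_map = masses.setdefault(iid, {})
        if row.site in site_map:
            raise DataValidationError(
                f"items row {i}: duplicate weighing for item {iid!r} at site {row.site!r}"
            )
        site_map[row.site] = mass
    for iid, (name, role, material) in meta.items():
        items[iid] = InventoryItem(item_id=iid, name=name, role=role,
                                   material=material, site_masses=masses[iid])

    if factor_table is not None:
        for item in items.values():
            if not factor_table.has(item.material):
                raise DataValidationError(
                    f"item {item.item_id!r}: material {item.material!r} is not in "
                    f"the emission-factor table; classify it to the closest WARM "
                    f"material or to {MIXED_MATERIAL!r}"
                )

    products_df = _read(products_path, _PRODUCT_COLS)
    products: dict[str, DrugProduct] = {}
    seen_keys: set[tuple] = set()
    for i, row in enumerate(products_df.itertuples(index=False), start=2):
        pid = row.product_id.strip()
        if pid in products:
            raise DataValidationError(f"products row {i}: duplicate product_id {pid!r}")
        product = DrugProduct(
            product_id=pid,
            agent=row.agent,
            dose_label=row.dose_label,
            formulation=FormulationType(row.formulation.strip()),
            doses_per_day=_as_float(row.doses_per_day, f"products row {i}"),
        )
        uk = (product.agent, product.dose_label, product.formulation)
        if uk in seen_keys:
            raise DataValidationError(
                f"products row {i}: duplicate (agent, dose_label, formulation) {uk}"
            )
        seen_keys.add(uk)
        products[pid] = product

    bom_df = _read(bom_path, _BOM_COLS)
    bom: list[BomEntry] = []
    for i, row in enumerate(bom_df.itertuples(index=False), start=2):
        if row.product_id not in products:
            raise DanglingReferenceError(
                f"bom row {i}: unknown product_id {row.product_id!r}"
            )
        if row.item_id not in items:
            raise DanglingReferenceError(f"bom row {i}: unknown item_id {row.item_id!r}")
        bom.append(BomEntry(product_id=row.product_id, item_id=row.item_id,
                            site=row.site,
                            count_per_dose=_as_float(row.count_per_dose, f"bom row {i}")))

    admin_df = _read(admin_bom_path, _ADMIN_COLS)
    admin: dict[str, dict[str, float]] = {}
    for i, row in enumerate(admin_df.itertuples(index=False), start=2):
        if row.item_id not in items:
            raise DanglingReferenceError(
                f"admin_daily row {i}: unknown item_id {row.item_id!r}"
            )
        if items[row.item_id].role is not ItemRole.ADMINISTRATION:
            raise DataValidationError(
                f"admin_daily row {i}: item {row.item_id!r} has role "
                f"{items[row.item_id].role.value!r}, expected 'administration'"
            )
        site_map = admin.setdefault(row.site, {})
        if row.item_id in site_map:
            raise DataValidationError(
                f"admin_daily row {i}: duplicate entry for item {row.item_id!r} "
                f"at site {row.site!r}"
            )
        site_map[row.item_id] = _as_float(row.count_per_day, f"admin_daily row {i}")

    return InventoryBundle(
        items=items,
        products=products,
        bom=bom,
        admin_daily={s: AdminDailyBom(site=s, entries=e) for s, e in admin.items()},
    )


def write_inventory(bundle: InventoryBundle, out_dir) -> None:
    """Canonical writer for a bundle (sorted rows, repr-precision floats)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lines = [",".join(_ITEM_COLS)]
    for iid in sorted(bundle.items):
        item = bundle.items[iid]
        for site in sorted(item.site_masses):
            lines.append(f"{iid},{item.name},{item.role.value},{item.material},"
                         f"{site},{item.site_masses[site]!r}")
    (out / "items.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = [",".join(_PRODUCT_COLS)]
    for pid in sorted(bundle.products):
        p = bundle.products[pid]
        lines.append(f"{pid},{p.agent},{p.dose_label},{p.formulation.value},"
                     f"{p.doses_per_day!r}")
    (out / "products.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = [",".join(_BOM_COLS)]
    for e in sorted(bundle.bom, key=lambda e: (e.product_id, e.site, e.item_id)):
        lines.append(f"{e.product_id},{e.item_id},{e.site},{e.count_per_dose!r}")
    (out / "bom.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = [",".join(_ADMIN_COLS)]
    for site in sorted(bundle.admin_daily):
        for item_id in sorted(bundle.admin_daily[site].entries):
            lines.append(f"{site},{item_id},{bundle.admin_daily[site].entries[item_id]!r}")
    (out / "admin_daily.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
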