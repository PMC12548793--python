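"""Reference tables: emission factors, GHG equivalencies, disposal scenarios, units.

Emission factors follow the EPA GHG Emission Factors Hub convention for waste:
metric tons of CO2-equivalent released per short ton of a given material managed
by a given disposal pathway (landfilled, recycled, or combusted). All internal
emission arithmetic in this package is carried in metric tons CO2e; conversion to
short tons happens only at report time.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataValidationError, MissingFactorError, SchemaError, UnitError

logger = logging.getLogger(__name__)

__all__ = [
    "MassUnit",
    "DisposalMethod",
    "EmissionFactorTable",
    "EquivalencyFactor",
    "DisposalScenario",
    "convert_mass",
    "normalize_material",
    "load_emission_factors",
    "write_emission_factors",
    "load_equivalency_factors",
    "load_scenario",
    "get_factor",
    "packaged_emission_factors",
    "packaged_equivalency_factors",
    "packaged_data_path",
]

#: grams per short ton (2000 lb avoirdupois, exact)
SHORT_TON_G = 907_184.74
#: grams per metric ton (exact)
METRIC_TON_G = 1_000_000.0

#: material name every packaged factor table must carry as the fallback class
MIXED_MATERIAL = "mixed"


class MassUnit(str, Enum):
    GRAM = "gram"
    KILOGRAM = "kilogram"
    METRIC_TON = "metric_ton"
    SHORT_TON = "short_ton"


_GRAMS_PER_UNIT = {
    MassUnit.GRAM: 1.0,
    MassUnit.KILOGRAM: 1_000.0,
    MassUnit.METRIC_TON: METRIC_TON_G,
    MassUnit.SHORT_TON: SHORT_TON_G,
}


def convert_mass(value: float, from_unit: MassUnit | str, to_unit: MassUnit | str) -> float:
    """Convert a mass between gram, kilogram, metric-ton, and short-ton units.

    Identity conversions return ``value`` unchanged (bitwise), so report columns
    derived from the same unit never pick up round-off.
    """
    try:
        fu = MassUnit(from_unit)
        tu = MassUnit(to_unit)
    except ValueError as exc:
        raise UnitError(f"unknown mass unit in conversion: {exc}") from None
    if fu is tu:
        return value
    return value * (_GRAMS_PER_UNIT[fu] / _GRAMS_PER_UNIT[tu])


class DisposalMethod(str, Enum):
    LANDFILLED = "landfilled"
    RECYCLED = "recycled"
    COMBUSTED = "combusted"

    @classmethod
    def parse(cls, raw: str) -> "DisposalMethod":
        """Parse a disposal-method name; 'incinerated' is accepted for combusted."""
        s = str(raw).strip().lower()
        if s == "incinerated":
            return cls.COMBUSTED
        try:
            return cls(s)
        except ValueError:
            raise DataValidationError(
                f"unknown disposal method {raw!r}; expected one of "
                f"{[m.value for m in cls]} (or 'incinerated')"
            ) from None


def normalize_material(name: str) -> str:
    """Canonical WARM-material key: trimmed, internal whitespace collapsed, casefolded."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class EquivalencyFactor:
    """One interpretive GHG equivalency (e.g. miles driven per mtCO2e)."""

    name: str
    unit_label: str
    mtco2e_per_unit: float


@dataclass
class EmissionFactorTable:
    """(material, disposal method) -> metric tons CO2e per short ton of waste.

    Negative factors are legal: EPA recycling pathways can carry net credits.
    """

    entries: dict[tuple[str, DisposalMethod], float]
    provenance: str

    def __post_init__(self):
        for (material, method), factor in self.entries.items():
            if not math.isfinite(float(factor)):
                raise DataValidationError(
                    f"non-finite factor for ({material!r}, {method.value})"
                )

    @property
    def materials(self) -> list[str]:
        seen: dict[str, None] = {}
        for material, _ in self.entries:
            seen.setdefault(material, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, material: str, method: DisposalMethod) -> float:
        key = (normalize_material(material), DisposalMethod(method))
        try:
            return self.entries[key]
        except KeyError:
            raise MissingFactorError(key[0], key[1].value) from None

    def has(self, material: str, method: DisposalMethod = DisposalMethod.LANDFILLED) -> bool:
        return (normalize_material(material), DisposalMethod(method)) in self.entries


@dataclass
class DisposalScenario:
    """Institution-level disposal configuration.

    One default pathway for everything plus per-material overrides, e.g. a
    hospital that landfills nonhazardous waste but recycles corrugated boxes.
    """

    default_method: DisposalMethod = DisposalMethod.LANDFILLED
    overrides: dict[str, DisposalMethod] = field(default_factory=dict)

    def __post_init__(self):
        self.default_method = DisposalMethod(self.default_method)
        self.overrides = {
            normalize_material(m): DisposalMethod(v) for m, v in self.overrides.items()
        }

    def method_for(self, material: str) -> DisposalMethod:
        return self.overrides.get(normalize_material(material), self.default_method)

    def validate_against(self, table: EmissionFactorTable) -> None:
        """Every override must resolve in the active factor table."""
        for material, method in self.overrides.items():
            if (material, method) not in table.entries:
                raise MissingFactorError(material, method.value)

    def describe(self) -> str:
        if not self.overrides:
            return self.default_method.value
        ov = "; ".join(f"{m}->{v.value}" for m, v in sorted(self.overrides.items()))
        return f"{self.default_method.value} ({ov})"


def get_factor(
    table: EmissionFactorTable, material: str, scenario: DisposalScenario
) -> float:
    """Resolve the disposal method through the scenario and return the factor.

    A missing (material, resolved-method) pair raises :class:`MissingFactorError`
    naming both — there is deliberately no silent fallback to the "mixed" class;
    assigning "mixed" is an inventory-classification decision made at data entry.
    """
    material = normalize_material(material)
    if not material:
        raise DataValidationError("material name must be non-empty")
    return table.get(material, scenario.method_for(material))


# ---------------------------------------------------------------------------
# file I/O

_FACTOR_COLUMNS = ["material", "disposal_method", "mtco2e_per_short_ton", "source"]
_EQUIV_COLUMNS = ["name", "unit_label", "mtco2e_per_unit"]


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    return df


def load_emission_factors(path) -> EmissionFactorTable:
    """Load an ``emission_factors.csv`` (material,disposal_method,mtco2e_per_short_ton,source).

    Material lookup is case-insensitive after whitespace normalization. Duplicate
    (material, method) keys and non-numeric factors are rejected with row numbers.
    """
    df = _read_table(path, _FACTOR_COLUMNS)
    entries: dict[tuple[str, DisposalMethod], float] = {}
    duplicates = []
    sources = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        material = normalize_material(row.material)
        if not material:
            raise DataValidationError(f"{Path(path).name} row {i}: empty material name")
        method = DisposalMethod.parse(row.disposal_method)
        try:
            factor = float(row.mtco2e_per_short_ton)
        except ValueError:
            raise DataValidationError(
                f"{Path(path).name} row {i}: non-numeric factor "
                f"{row.mtco2e_per_short_ton!r} for ({material}, {method.value})"
            ) from None
        key = (material, method)
        if key in entries:
            duplicates.append((i, material, method.value))
        entries[key] = factor
        if row.source:
            sources.append(row.source)
    if duplicates:
        listing = "; ".join(f"row {i}: ({m}, {d})" for i, m, d in duplicates)
        raise DataValidationError(f"duplicate (material, disposal_method) keys: {listing}")
    provenance = sources[0] if sources else str(Path(path).name)
    return EmissionFactorTable(entries=entries, provenance=provenance)


def write_emission_factors(table: EmissionFactorTable, path) -> None:
    """Canonical writer: sorted keys, repr-precision floats, byte-stable."""
    lines = [",".join(_FACTOR_COLUMNS)]
    for (material, method), factor in sorted(
        table.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        mat = f'"{material}"' if "," in material else material
        lines.append(f"{mat},{method.value},{factor!r},{table.provenance}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_equivalency_factors(path) -> list[EquivalencyFactor]:
    """Load ``equivalencies.csv``; file order defines report column order."""
    df = _read_table(path, _EQUIV_COLUMNS)
    out: list[EquivalencyFactor] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = str(row.name).strip()
        if not name:
            raise DataValidationError(f"row {i}: empty equivalency name")
        if name in seen:
            raise DataValidationError(f"row {i}: duplicate equivalency name {name!r}")
        seen.add(name)
        try:
            factor = float(row.mtco2e_per_unit)
        except ValueError:
            raise DataValidationError(
                f"row {i}: non-numeric equivalency factor {row.mtco2e_per_unit!r}"
            ) from None
        if not factor > 0:
            raise DataValidationError(
                f"row {i}: equivalency factor must be positive, got {factor}"
            )
        out.append(EquivalencyFactor(name=name, unit_label=str(row.unit_label).strip(),
                                     mtco2e_per_unit=factor))
    return out


def load_scenario(path) -> DisposalScenario:
    """Load a ``scenario.json`` disposal configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise DataValidationError("scenario.json must contain a JSON object")
    default = DisposalMethod.parse(raw.get("default_method", "landfilled"))
    overrides = {
        str(mat): DisposalMethod.parse(meth)
        for mat, meth in (raw.get("overrides") or {}).items()
    }
    return DisposalScenario(default_method=default, overrides=overrides)


def packaged_data_path(*parts: str) -> Path:
    """Path to a file shipped under ``abx_carbon/data``."""
    return Path(resources.files("abx_carbon").joinpath("data", *parts))  # type: ignore[arg-type]


def packaged_emission_factors() -> EmissionFactorTable:
    table = load_emission_factors(packaged_data_path("emission_factors.csv"))
    if not table.has(MIXED_MATERIAL):
        raise DataValidationError("packaged factor table lacks the 'mixed' fallback class")
    return table


def packaged_equivalency_factors() -> list[EquivalencyFactor]:
    return load_equivalency_factors(packaged_data_path("equivalencies.csv"))


def warn_if_net_negative(total_mtco2e: float, scenario: DisposalScenario) -> None:
    """Recycling credits can push a scenario's total below zero; surface that."""
    if total_mtco2e < 0:
        logger.warning(
            "net-negative total emissions (%.6g mtCO2e) under scenario %s; "
            "this is expected only when recycling credits dominate",
            total_mtco2e,
            scenario.describe(),
        )
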