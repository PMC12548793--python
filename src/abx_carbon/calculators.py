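"""User-facing DOT / Dose / Drug-Product calculators and the report writer.

Each calculator takes utilization records (per-agent IV days of therapy, per
agent-and-strength dose counts, or per-product dose counts), multiplies them by
the corresponding emission factors, and produces a :class:`Report` whose rows
carry CO2e (short and metric tons), waste mass, and a configurable set of GHG
equivalencies (miles driven, gasoline consumed, ...), plus a totals row that is
the column-wise sum. Summation runs in canonical key order so totals are
bit-stable across platforms.
"""

from __future__ import annotations

import csv
import difflib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .engine import AgentDoseFactor, AgentFactor, EmissionResult
from .errors import DataValidationError, SchemaError, UnmatchedKeyError
from .reference_data import (
    EquivalencyFactor,
    MassUnit,
    convert_mass,
    packaged_data_path,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UsageRecord",
    "ReportRow",
    "Report",
    "NormalizedAgent",
    "normalize_agent_name",
    "load_synonyms",
    "equivalency_values",
    "compute_dot_report",
    "compute_dose_report",
    "compute_product_report",
    "write_report",
    "read_report_json",
    "load_usage_dot",
    "load_usage_dose",
    "load_usage_product",
]


@dataclass(frozen=True)
class UsageRecord:
    """One utilization row: a key (agent / agent+dose / product) and a quantity."""

    key: tuple[str, ...]
    quantity: float

    def __post_init__(self):
        if self.quantity < 0:
            raise DataValidationError(
                f"usage quantity for {self.key} must be >= 0, got {self.quantity}"
            )


@dataclass
class ReportRow:
    key: tuple[str, ...]
    quantity: float
    co2e_metric_tons: float
    co2e_short_tons: float
    waste_mass_g: float
    waste_mass_short_tons: float
    equivalencies: dict[str, float]


@dataclass
class Report:
    key_fields: tuple[str, ...]
    rows: list[ReportRow]
    totals: ReportRow
    metadata: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# agent-name normalization


@dataclass(frozen=True)
class NormalizedAgent:
    name: str
    matched: bool


def load_synonyms(path=None) -> dict[str, str]:
    """Load the raw->canonical agent synonym table (salt suffixes, brand names)."""
    path = Path(path) if path is not None else packaged_data_path("agent_synonyms.csv")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("raw", "canonical"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return {_canonical_string(r.raw): _canonical_string(r.canonical)
            for r in df.itertuples(index=False)}


def _canonical_string(raw: str) -> str:
    """Lower-case, trim, collapse whitespace, unify '/' and ' - ' to '-'."""
    s = " ".join(str(raw).split()).casefold()
    s = s.replace("/", "-")
    while " -" in s or "- " in s:
        s = s.replace(" -", "-").replace("- ", "-")
    return s


def normalize_agent_name(
    raw: str,
    synonyms: dict[str, str] | None = None,
    known: set[str] | None = None,
) -> NormalizedAgent:
    """Normalize an agent spelling for matching against factor rows.

    Trims, case-folds, unifies separator spellings ("piperacillin/tazobactam"
    and "piperacillin-tazobactam" become one key) and applies the synonym table
    ("vancomycin HCl" -> "vancomycin"). When a ``known`` vocabulary is supplied,
    a name that still does not match is returned flagged — never guessed.
    """
    if not str(raw).strip():
        raise DataValidationError("agent name must be non-empty")
    if synonyms is None:
        synonyms = load_synonyms()
    name = _canonical_string(raw)
    name = synonyms.get(name, name)
    matched = True if known is None else name in known
    return NormalizedAgent(name=name, matched=matched)


# ---------------------------------------------------------------------------
# report assembly


def equivalency_values(
    mtco2e: float, equivalencies: list[EquivalencyFactor]
) -> dict[str, float]:
    """Express an emission total in each interpretive equivalency unit."""
    return {eq.name: mtco2e / eq.mtco2e_per_unit for eq in equivalencies}


def _make_row(key, quantity, mtco2e, waste_g, equivalencies) -> ReportRow:
    return ReportRow(
        key=key,
        quantity=quantity,
        co2e_metric_tons=mtco2e,
        co2e_short_tons=convert_mass(mtco2e, MassUnit.METRIC_TON, MassUnit.SHORT_TON),
        waste_mass_g=waste_g,
        waste_mass_short_tons=convert_mass(waste_g, MassUnit.GRAM, MassUnit.SHORT_TON),
        equivalencies=equivalency_values(mtco2e, equivalencies),
    )


def _build_report(entries, key_fields, equivalencies, metadata) -> Report:
    """entries: list of (key_tuple, quantity, mtco2e_per_unit, waste_g_per_unit)."""
    rows = []
    for key, quantity, f_mtco2e, f_waste in sorted(entries, key=lambda e: e[0]):
        rows.append(_make_row(key, quantity, quantity * f_mtco2e,
                              quantity * f_waste, equivalencies))
    total_mtco2e = sum(r.co2e_metric_tons for r in rows)
    total_waste = sum(r.waste_mass_g for r in rows)
    totals = _make_row(("TOTAL",) * len(key_fields),
                       sum(r.quantity for r in rows),
                       total_mtco2e, total_waste, equivalencies)
    if total_mtco2e < 0:
        logger.warning("net-negative report total: %.6g mtCO2e", total_mtco2e)
    return Report(key_fields=key_fields, rows=rows, totals=totals,
                  metadata=dict(metadata or {}))


def _match(name: str, table: dict, synonyms) -> str:
    norm = normalize_agent_name(name, synonyms=synonyms, known=set(table))
    if not norm.matched:
        candidates = difflib.get_close_matches(norm.name, sorted(table), n=3, cutoff=0.6)
        raise UnmatchedKeyError(name, candidates)
    return norm.name


def compute_dot_report(
    usage: list[UsageRecord],
    factors: list[AgentFactor],
    equivalencies: list[EquivalencyFactor],
    synonyms: dict[str, str] | None = None,
    metadata: dict[str, str] | None = None,
) -> Report:
    """Per-agent report from IV days-of-therapy counts (NHSN line-listing style).

    Rows with zero DOT are emitted as zeros, not dropped, so a stewardship team
    sees its whole agent list in the output.
    """
    if synonyms is None:
        synonyms = load_synonyms()
    table = {f.agent: f for f in factors}
    entries = []
    for record in usage:
        agent = _match(record.key[0], table, synonyms)
        f = table[agent]
        entries.append(((agent,), record.quantity, f.mtco2e_per_dot, f.waste_g_per_dot))
    return _build_report(entries, ("agent",), equivalencies, metadata)


def compute_dose_report(
    usage: list[UsageRecord],
    factors: list[AgentDoseFactor],
    equivalencies: list[EquivalencyFactor],
    synonyms: dict[str, str] | None = None,
    metadata: dict[str, str] | None = None,
) -> Report:
    """Per-(agent, dose strength) report from administered-dose counts."""
    if synonyms is None:
        synonyms = load_synonyms()
    table = {(f.agent, f.dose_label): f for f in factors}
    agents = {a for a, _ in table}
    entries = []
    for record in usage:
        raw_agent, dose_label = record.key
        agent = _match(raw_agent, {a: None for a in agents}, synonyms)
        key = (agent, str(dose_label).strip())
        if key not in table:
            labels = sorted(lbl for a, lbl in table if a == agent)
            raise UnmatchedKeyError(key, labels)
        f = table[key]
        entries.append((key, record.quantity, f.mtco2e_per_dose, f.waste_g_per_dose))
    return _build_report(entries, ("agent", "dose_label"), equivalencies, metadata)


def compute_product_report(
    usage: list[UsageRecord],
    product_results: dict[str, EmissionResult],
    equivalencies: list[EquivalencyFactor],
    metadata: dict[str, str] | None = None,
) -> Report:
    """Per-product report from dose counts, using un-averaged per-product results."""
    entries = []
    for record in usage:
        pid = record.key[0].strip()
        if pid not in product_results:
            candidates = difflib.get_close_matches(pid, sorted(product_results), n=3,
                                                   cutoff=0.6)
            raise UnmatchedKeyError(pid, candidates)
        r = product_results[pid]
        entries.append(((pid,), record.quantity, r.mtco2e, r.waste_mass_g))
    return _build_report(entries, ("product_id",), equivalencies, metadata)


# ---------------------------------------------------------------------------
# usage-file loaders

def _load_usage(path, cols, key_cols, qty_col) -> list[UsageRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            qty = float(getattr(row, qty_col))
        except ValueError:
            raise DataValidationError(
                f"{path.name} row {i}: non-numeric quantity "
                f"{getattr(row, qty_col)!r}"
            ) from None
        records.append(UsageRecord(
            key=tuple(getattr(row, c) for c in key_cols), quantity=qty))
    return records


def load_usage_dot(path) -> list[UsageRecord]:
    return _load_usage(path, ["agent", "iv_dot"], ["agent"], "iv_dot")


def load_usage_dose(path) -> list[UsageRecord]:
    return _load_usage(path, ["agent", "dose_label", "n_doses"],
                       ["agent", "dose_label"], "n_doses")


def load_usage_product(path) -> list[UsageRecord]:
    return _load_usage(path, ["product_id", "n_doses"], ["product_id"], "n_doses")


# ---------------------------------------------------------------------------
# serialization

_NUMERIC_COLS = [
    "quantity",
    "co2e_short_tons",
    "co2e_metric_tons",
    "waste_mass_short_tons",
    "waste_mass_g",
]


def _row_values(row: ReportRow) -> list[float]:
    return [row.quantity, row.co2e_short_tons, row.co2e_metric_tons,
            row.waste_mass_short_tons, row.waste_mass_g,
            *row.equivalencies.values()]


def report_to_dict(report: Report) -> dict:
    eq_names = list(report.totals.equivalencies)

    def row_dict(row: ReportRow) -> dict:
        d = dict(zip(report.key_fields, row.key))
        d.update(zip(_NUMERIC_COLS, _row_values(row)[: len(_NUMERIC_COLS)]))
        d["equivalencies"] = dict(row.equivalencies)
        return d

    return {
        "metadata": dict(report.metadata),
        "key_fields": list(report.key_fields),
        "equivalency_names": eq_names,
        "rows": [row_dict(r) for r in report.rows],
        "totals": row_dict(report.totals),
    }


def report_from_dict(d: dict) -> Report:
    key_fields = tuple(d["key_fields"])

    def parse_row(rd: dict) -> ReportRow:
        return ReportRow(
            key=tuple(rd[k] for k in key_fields),
            quantity=rd["quantity"],
            co2e_metric_tons=rd["co2e_metric_tons"],
            co2e_short_tons=rd["co2e_short_tons"],
            waste_mass_g=rd["waste_mass_g"],
            waste_mass_short_tons=rd["waste_mass_short_tons"],
            equivalencies=dict(rd["equivalencies"]),
        )

    return Report(
        key_fields=key_fields,
        rows=[parse_row(r) for r in d["rows"]],
        totals=parse_row(d["totals"]),
        metadata=dict(d.get("metadata", {})),
    )


def read_report_json(path) -> Report:
    with open(path, encoding="utf-8") as fh:
        return report_from_dict(json.load(fh))


def report_to_csv_text(report: Report) -> str:
    """Deterministic CSV serialization: metadata header comments, full-precision
    value columns, then 2-decimal display companions, then the totals row."""
    eq_names = list(report.totals.equivalencies)
    buf = io.StringIO()
    for k in sorted(report.metadata):
        buf.write(f"# {k}: {report.metadata[k]}\n")
    writer = csv.writer(buf, lineterminator="\n")
    value_cols = _NUMERIC_COLS + eq_names
    writer.writerow([*report.key_fields, *value_cols,
                     *[f"{c} (2dp)" for c in value_cols]])
    for row in [*report.rows, report.totals]:
        values = _row_values(row)
        writer.writerow([*row.key,
                         *[repr(float(v)) for v in values],
                         *[f"{v:.2f}" for v in values]])
    return buf.getvalue()


def write_report(report: Report, path, format: str = "csv") -> None:
    """Write a report as CSV (spreadsheet-friendly) or JSON (lossless)."""
    path = Path(path)
    if format == "csv":
        path.write_text(report_to_csv_text(report), encoding="utf-8")
    elif format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n",
                        encoding="utf-8")
    else:
        raise DataValidationError(f"unknown report format {format!r}; use csv or json")
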