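"""Readers, writers and nomenclature maps for residue-monitoring files.

Two tabular dialects are supported, one row per sample x analyte
determination, uncompressed CSV:

* US-PDP-like: ``sample_id, year, food, food_form, origin, state, claim,
  analyte, conc_ppm, loq_ppm, lod_ppm`` where ``origin`` is ``domestic`` or
  an ISO country code.
* UK-FSA-like: the same columns plus ``quarter`` and ``origin_category``
  (``domestic | eu_import | non_eu_import``); files are quarterly and are
  combined by calendar year of sampling.

Non-detects must be explicit zero-concentration rows carrying their LOQ, so
N (samples tested) is unambiguous; a missing row means "not analyzed".
Concentrations are ppm (mg/kg); a ``unit="ug_per_kg"`` dialect flag converts
on read.  Analyte and food nomenclature is reconciled through user-supplied
mapping tables; measurements of metabolites/moieties mapped to one analyte
within a sample are combined as a weighted sum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    DataIntegrityError,
    FoodServing,
    InvalidInputError,
    Measurement,
    SampleRecord,
    ToxicityThreshold,
)

__all__ = [
    "IngestReport",
    "AnalyteMap",
    "FoodMap",
    "read_pdp",
    "read_fsa",
    "write_pdp",
    "write_fsa",
    "apply_maps",
    "load_thresholds",
    "load_servings",
    "load_analyte_map",
    "load_food_map",
]

PDP_COLUMNS = [
    "sample_id",
    "year",
    "food",
    "food_form",
    "origin",
    "state",
    "claim",
    "analyte",
    "conc_ppm",
    "loq_ppm",
    "lod_ppm",
]
FSA_COLUMNS = PDP_COLUMNS + ["quarter", "origin_category"]

_CLAIMS = {"organic", "ipm", "pesticide-free", "none", ""}


@dataclass
class IngestReport:
    """Row-level diagnostics accumulated while reading residue files."""

    n_rows: int = 0
    n_failed: int = 0
    errors: list[str] = field(default_factory=list)
    unmapped_analytes: dict[str, int] = field(default_factory=dict)
    unmapped_foods: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record_error(self, msg: str) -> None:
        self.n_failed += 1
        if len(self.errors) < 200:
            self.errors.append(msg)

    def render(self) -> str:
        lines = [f"rows read: {self.n_rows}", f"rows failed: {self.n_failed}"]
        lines += [f"ERROR {e}" for e in self.errors]
        if self.unmapped_analytes:
            lines.append("unmapped analyte labels (excluded from DRI computation):")
            lines += [f"  {k}: {v} row(s)" for k, v in sorted(self.unmapped_analytes.items())]
        if self.unmapped_foods:
            lines.append("unmapped food labels (kept under source label):")
            lines += [f"  {k}: {v} row(s)" for k, v in sorted(self.unmapped_foods.items())]
        lines += [f"WARNING {w}" for w in self.warnings]
        return "\n".join(lines)


def _parse_float(text: str, column: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable {column}: {text!r}") from None


def _read_dialect(
    source,
    columns: Sequence[str],
    *,
    program: str,
    unit: str,
    max_bad_fraction: float,
    report: IngestReport,
    year: int | None = None,
    quarter: int | None = None,
) -> list[SampleRecord]:
    if isinstance(source, (str, Path)):
        handle = open(source, newline="")
    else:
        handle = source
    scale = {"ppm": 1.0, "mg_per_kg": 1.0, "ug_per_kg": 1e-3}[unit]
    try:
        reader = csv.DictReader(handle)
        unknown = set(reader.fieldnames or []) - set(columns)
        missing = set(columns) - set(reader.fieldnames or []) - {"quarter", "origin_category"}
        if unknown or missing:
            raise InvalidInputError(
                f"schema mismatch: unknown columns {sorted(unknown)}, missing {sorted(missing)}"
            )
        by_sample: dict[str, dict] = {}
        seen_pairs: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            report.n_rows += 1
            try:
                conc = _parse_float(row["conc_ppm"], "conc_ppm") * scale
                loq = _parse_float(row["loq_ppm"], "loq_ppm") * scale
                lod = _parse_float(row.get("lod_ppm") or "0", "lod_ppm") * scale
                row_year = int(row["year"]) if year is None else year
                row_quarter = quarter
                if "quarter" in (reader.fieldnames or []) and row.get("quarter"):
                    row_quarter = int(row["quarter"])
                if row_quarter is not None and not 1 <= row_quarter <= 4:
                    raise ValueError(f"quarter outside 1-4: {row_quarter}")
                claim = (row.get("claim") or "none").strip().lower() or "none"
                if claim not in _CLAIMS:
                    raise ValueError(f"unknown market claim {claim!r}")
                sid = row["sample_id"].strip()
                analyte = row["analyte"].strip()
                if (sid, analyte) in seen_pairs:
                    raise DataIntegrityError(
                        f"duplicate (sample, analyte) row: {sid!r}/{analyte!r}"
                    )
                seen_pairs.add((sid, analyte))
                origin = (row.get("origin") or "").strip()
                rec = by_sample.get(sid)
                if rec is None:
                    rec = by_sample[sid] = {
                        "sample_id": sid,
                        "food_id": row["food"].strip(),
                        "food_form": (row.get("food_form") or "any").strip() or "any",
                        "year": row_year,
                        "quarter": row_quarter,
                        "origin_country": origin,
                        "origin_state": (row.get("state") or None) or None,
                        "origin_category": (row.get("origin_category") or None),
                        "claim": claim,
                        "program": program,
                        "measurements": [],
                    }
                rec["measurements"].append(
                    Measurement(analyte_id=analyte, conc_ppm=conc, loq_ppm=loq, lod_ppm=lod)
                )
            except DataIntegrityError:
                raise
            except (ValueError, KeyError) as exc:
                report.record_error(f"line {lineno}: {exc}")
        if report.n_rows and report.n_failed / report.n_rows > max_bad_fraction:
            raise InvalidInputError(
                f"{report.n_failed}/{report.n_rows} rows failed "
                f"(> {max_bad_fraction:.0%}); aborting file"
            )
        return [SampleRecord(**rec) for rec in by_sample.values()]
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def read_pdp(
    source,
    *,
    unit: str = "ppm",
    max_bad_fraction: float = 0.10,
    report: IngestReport | None = None,
) -> tuple[list[SampleRecord], IngestReport]:
    """Read a US-PDP-like CSV into sample records.

    ``origin == "domestic"`` is normalised to country code ``US``.
    """
    report = report if report is not None else IngestReport()
    records = _read_dialect(
        source,
        PDP_COLUMNS,
        program="us_pdp",
        unit=unit,
        max_bad_fraction=max_bad_fraction,
        report=report,
    )
    for r in records:
        if r.origin_country.lower() == "domestic":
            r.origin_country = "US"
    return records, report


def read_fsa(
    sources: Iterable,
    *,
    unit: str = "ppm",
    max_bad_fraction: float = 0.10,
    report: IngestReport | None = None,
) -> tuple[list[SampleRecord], IngestReport]:
    """Read quarterly UK-FSA-like CSVs, combined by calendar year of sampling.

    Each file supplies ``year`` and ``quarter`` columns; records keep the
    sampling year printed in the file (mixed-year files split accordingly).
    A year covered by a single quarter gets a low-coverage warning.
    """
    report = report if report is not None else IngestReport()
    records: list[SampleRecord] = []
    for source in sources:
        records.extend(
            _read_dialect(
                source,
                FSA_COLUMNS,
                program="uk_fsa",
                unit=unit,
                max_bad_fraction=max_bad_fraction,
                report=report,
            )
        )
    for r in records:
        if r.origin_category is None:
            r.origin_category = (
                "domestic" if r.origin_country.upper() == "UK" else "non_eu_import"
            )
        if r.origin_country.lower() == "domestic":
            r.origin_country = "UK"
    quarters_by_year: dict[int, set[int]] = {}
    for r in records:
        if r.quarter is not None:
            quarters_by_year.setdefault(r.year, set()).add(r.quarter)
    for year, qs in sorted(quarters_by_year.items()):
        if len(qs) < 4:
            report.warnings.append(
                f"year {year}: only quarter(s) {sorted(qs)} present; "
                "annual summaries have low coverage"
            )
    return records, report


def _records_rows(records: Iterable[SampleRecord], fsa: bool):
    for r in records:
        for m in r.measurements:
            row = {
                "sample_id": r.sample_id,
                "year": r.year,
                "food": r.food_id,
                "food_form": r.food_form,
                "origin": r.origin_country,
                "state": r.origin_state or "",
                "claim": r.claim,
                "analyte": m.analyte_id,
                "conc_ppm": repr(m.conc_ppm),
                "loq_ppm": repr(m.loq_ppm),
                "lod_ppm": repr(m.lod_ppm),
            }
            if fsa:
                row["quarter"] = r.quarter if r.quarter is not None else ""
                row["origin_category"] = r.origin_category or ""
            yield row


def _write(records, path, columns, fsa):
    out = open(path, "w", newline="") if isinstance(path, (str, Path)) else path
    try:
        writer = csv.DictWriter(out, fieldnames=columns)
        writer.writeheader()
        for row in _records_rows(records, fsa):
            writer.writerow(row)
    finally:
        if isinstance(path, (str, Path)):
            out.close()


def write_pdp(records: Iterable[SampleRecord], path) -> None:
    """Write records in the PDP-like schema (floats via ``repr``, lossless)."""
    _write(records, path, PDP_COLUMNS, fsa=False)


def write_fsa(records: Iterable[SampleRecord], path) -> None:
    _write(records, path, FSA_COLUMNS, fsa=True)


# ---------------------------------------------------------------------------
# nomenclature maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyteMapEntry:
    analyte_id: str
    group_role: str = "parent"  # parent | metabolite | moiety
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidInputError(f"map weight must be > 0, got {self.weight}")


@dataclass
class AnalyteMap:
    """source analyte label -> (canonical id, role, concentration weight).

    Weighted sums express moiety rules (default weight 1: plain addition of
    parent and metabolite concentrations mapped to the same canonical id).
    """

    entries: dict[str, AnalyteMapEntry] = field(default_factory=dict)

    def lookup(self, label: str) -> AnalyteMapEntry | None:
        return self.entries.get(label) or self.entries.get(label.strip().lower())


@dataclass
class FoodMap:
    """(source food label, source form label) -> (food_id, food_form)."""

    entries: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def lookup(self, food: str, form: str) -> tuple[str, str] | None:
        for key in ((food, form), (food, "any"), (food.strip().lower(), form)):
            if key in self.entries:
                return self.entries[key]
        return None


def apply_maps(
    records: Sequence[SampleRecord],
    analyte_map: AnalyteMap | None = None,
    food_map: FoodMap | None = None,
    report: IngestReport | None = None,
) -> tuple[list[SampleRecord], IngestReport]:
    """Canonicalise labels; combine same-target measurements within a sample.

    Unmapped analyte labels are excluded from downstream DRI computation and
    enumerated once each in the report; unmapped food labels are kept under
    their source label and enumerated.  Applying the maps twice equals
    applying them once (canonical ids map to themselves implicitly).
    """
    report = report if report is not None else IngestReport()
    out: list[SampleRecord] = []
    for rec in records:
        food_id, food_form = rec.food_id, rec.food_form
        if food_map is not None and food_map.entries:
            mapped = food_map.lookup(food_id, food_form)
            if mapped is not None:
                food_id, food_form = mapped
            elif not any(v == (food_id, food_form) for v in food_map.entries.values()):
                report.unmapped_foods[food_id] = report.unmapped_foods.get(food_id, 0) + 1
        combined: dict[str, dict] = {}
        for m in rec.measurements:
            if analyte_map is not None and analyte_map.entries:
                entry = analyte_map.lookup(m.analyte_id)
                if entry is None:
                    if any(e.analyte_id == m.analyte_id for e in analyte_map.entries.values()):
                        entry = AnalyteMapEntry(m.analyte_id)  # already canonical
                    else:
                        report.unmapped_analytes[m.analyte_id] = (
                            report.unmapped_analytes.get(m.analyte_id, 0) + 1
                        )
                        continue
            else:
                entry = AnalyteMapEntry(m.analyte_id)
            slot = combined.setdefault(
                entry.analyte_id, {"conc": 0.0, "loq": None, "lod": None}
            )
            slot["conc"] += entry.weight * m.conc_ppm
            slot["loq"] = m.loq_ppm if slot["loq"] is None else min(slot["loq"], m.loq_ppm)
            slot["lod"] = m.lod_ppm if slot["lod"] is None else min(slot["lod"], m.lod_ppm)
        out.append(
            SampleRecord(
                sample_id=rec.sample_id,
                food_id=food_id,
                food_form=food_form,
                year=rec.year,
                quarter=rec.quarter,
                origin_country=rec.origin_country,
                origin_state=rec.origin_state,
                origin_category=rec.origin_category,
                claim=rec.claim,
                program=rec.program,
                measurements=[
                    Measurement(a, s["conc"], s["loq"], s["lod"])
                    for a, s in combined.items()
                ],
            )
        )
    return out, report


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------


def load_thresholds(path) -> dict[str, ToxicityThreshold]:
    """Threshold CSV: analyte_id, display_name, family, ptype,
    crfd_mg_per_kg_bw_day, fqpa_factor, banned_oc (0/1), authority."""
    df = pd.read_csv(path)
    out: dict[str, ToxicityThreshold] = {}
    for row in df.itertuples(index=False):
        out[row.analyte_id] = ToxicityThreshold(
            analyte_id=row.analyte_id,
            display_name=getattr(row, "display_name", row.analyte_id),
            family=str(getattr(row, "family", "")),
            ptype=str(getattr(row, "ptype", "other")),
            crfd=float(row.crfd_mg_per_kg_bw_day),
            fqpa_factor=float(getattr(row, "fqpa_factor", 1.0)),
            banned_oc=bool(int(getattr(row, "banned_oc", 0))),
            authority=str(getattr(row, "authority", "")),
        )
    return out


def load_servings(path) -> dict[tuple[str, str], FoodServing]:
    """Serving CSV: food_id, food_form, racc_g[, serv_g, bw_kg]."""
    df = pd.read_csv(path)
    out: dict[tuple[str, str], FoodServing] = {}
    for row in df.itertuples(index=False):
        form = str(getattr(row, "food_form", "any") or "any")
        serv = getattr(row, "serv_g", None)
        bw = getattr(row, "bw_kg", None)
        out[(row.food_id, form)] = FoodServing(
            food_id=row.food_id,
            food_form=form,
            racc_g=float(row.racc_g) if not pd.isna(row.racc_g) else None,
            serv_g=float(serv) if serv is not None and not pd.isna(serv) else None,
            bw_kg=float(bw) if bw is not None and not pd.isna(bw) else 16.0,
        )
    return out


def load_analyte_map(path) -> AnalyteMap:
    """Map CSV: source_label, analyte_id[, group_role, weight]."""
    df = pd.read_csv(path)
    entries = {}
    for row in df.itertuples(index=False):
        entries[str(row.source_label)] = AnalyteMapEntry(
            analyte_id=str(row.analyte_id),
            group_role=str(getattr(row, "group_role", "parent") or "parent"),
            weight=float(getattr(row, "weight", 1.0)),
        )
    return AnalyteMap(entries)


def load_food_map(path) -> FoodMap:
    """Map CSV: source_food_label, source_form_label, food_id, food_form."""
    df = pd.read_csv(path)
    entries = {}
    for row in df.itertuples(index=False):
        entries[(str(row.source_food_label), str(row.source_form_label))] = (
            str(row.food_id),
            str(row.food_form),
        )
    return FoodMap(entries)
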