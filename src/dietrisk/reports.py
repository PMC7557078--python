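"""Ranked DRI report tables and stratum comparisons.

The report family aggregates food x analyte summaries along four axes:
per food across analytes (kind 3), per analyte across foods (kind 4), all
foods in a year (kind 5), all analytes in a year (kind 6, optionally split
into a top-k block plus an "others" block), by pesticide type (kind 7), and
by food group (kind 8, a grouped variant of kind 5).  Rows are ranked by
FS-DRI descending with deterministic tie-breaking (then DRI-M descending,
then label); percent shares are computed from unrounded values and summary
rows equal column sums at full precision.  Rounding to 3 significant
figures / 1-decimal percents happens only at rendering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    Diagnostics,
    ResidueSummary,
    SampleRecord,
    ToxicityThreshold,
    crfc,
    dri_m,
    fs_dri,
    summarize_samples,
    _lookup_serving,
)
from .filters import SelectionSpec, apply_rule_of_10, select

__all__ = [
    "EmptyReportWarning",
    "DriContext",
    "CrfcTable",
    "ReportTable",
    "StratumTotals",
    "compute_rows",
    "report_food",
    "report_pesticide",
    "report_all_foods",
    "report_all_foods_from_rows",
    "report_all_pesticides",
    "report_all_pesticides_from_rows",
    "report_by_type",
    "stratum_totals",
    "compare_strata",
    "compare_strata_records",
    "sigfig",
    "report_filename",
]


class EmptyReportWarning(UserWarning):
    """Emitted when a selection yields no rows; the report is returned empty."""


def sigfig(x: float, n: int = 3) -> float:
    """Round-half-up to *n* significant figures (spreadsheet convention)."""
    if x is None or not math.isfinite(x) or x == 0:
        return x
    x = float(x)
    d = Decimal(repr(x))
    shift = n - 1 - math.floor(math.log10(abs(x)))
    return float(d.quantize(Decimal(1).scaleb(-shift), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# cRfC resolution
# ---------------------------------------------------------------------------


@dataclass
class DriContext:
    """Resolves the reference concentration for each summary row.

    Holds the toxicity-threshold and serving tables; analytes without a
    threshold are excluded and counted in :attr:`diagnostics`, while a
    missing serving for a food that has rows is an error (servings are part
    of the run configuration, thresholds track lab panels).
    """

    thresholds: Mapping[str, ToxicityThreshold]
    servings: Mapping
    diagnostics: Diagnostics = field(default_factory=Diagnostics)

    def resolve(self, s: ResidueSummary) -> tuple[float, float] | None:
        thr = self.thresholds.get(s.analyte_id)
        if thr is None:
            self.diagnostics.missing_threshold[s.analyte_id] += 1
            return None
        serving = _lookup_serving(self.servings, s.food_id, s.food_form)
        return crfc(thr, serving), serving.serv_g

    def ptype(self, analyte_id: str) -> str:
        thr = self.thresholds.get(analyte_id)
        return thr.ptype if thr is not None else "unknown"


@dataclass
class CrfcTable:
    """Direct (food or analyte keyed) cRfC lookup, e.g. from a printed table."""

    by_key: Mapping[tuple, tuple[float, float]]  # key -> (crfc_ppm, serv_g)
    ptypes: Mapping[str, str] = field(default_factory=dict)
    diagnostics: Diagnostics = field(default_factory=Diagnostics)

    def resolve(self, s: ResidueSummary) -> tuple[float, float] | None:
        for key in (
            (s.food_id, s.food_form, s.analyte_id),
            (s.food_id, s.analyte_id),
            (s.analyte_id,),
        ):
            if key in self.by_key:
                return self.by_key[key]
        self.diagnostics.missing_threshold[s.analyte_id] += 1
        return None

    def ptype(self, analyte_id: str) -> str:
        return self.ptypes.get(analyte_id, "unknown")


# ---------------------------------------------------------------------------
# row assembly and ranking
# ---------------------------------------------------------------------------

ROW_COLUMNS = [
    "food_id",
    "food_form",
    "analyte_id",
    "year",
    "n",
    "np",
    "pct_positive",
    "mean_ppm",
    "crfc_ppm",
    "serv_g",
    "dri_m",
    "fs_dri",
]


def compute_rows(summaries: Iterable[ResidueSummary], ctx) -> pd.DataFrame:
    """Per-summary DRI rows; summaries without positives or thresholds are
    omitted (and counted in the context's diagnostics)."""
    rows = []
    for s in summaries:
        if s.n_positive == 0:
            ctx.diagnostics.no_positives += 1
            continue
        resolved = ctx.resolve(s)
        if resolved is None:
            continue
        crfc_ppm, serv_g = resolved
        d = dri_m(s, crfc_ppm).value
        f = fs_dri(s, crfc_ppm).value
        rows.append(
            (
                s.food_id,
                s.food_form,
                s.analyte_id,
                s.year,
                s.n_tested,
                s.n_positive,
                s.pct_positive,
                s.mean_positives_ppm,
                crfc_ppm,
                serv_g,
                d,
                f,
            )
        )
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


def _rank(df: pd.DataFrame, label_col: str) -> pd.DataFrame:
    df = df.sort_values(
        by=["fs_dri", "dri_m", label_col],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    total = df.fs_dri.sum()
    df["pct_fs_dri"] = 100.0 * df.fs_dri / total if total > 0 else 0.0
    return df


@dataclass
class ReportTable:
    """A ranked result table plus its summary (bottom-row) statistics."""

    kind: str
    frame: pd.DataFrame
    summary: dict
    title: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    def rounded(self, percents: int = 1, sig: int = 3) -> pd.DataFrame:
        out = self.frame.copy()
        for col in out.columns:
            if col.startswith("pct"):
                out[col] = out[col].map(
                    lambda v: round(v * 100, percents) / 1.0
                    if col == "pct_positive"
                    else round(v, percents)
                )
            elif out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: sigfig(v, sig))
        return out

    def to_csv(self, path, full_precision: bool = False) -> None:
        frame = self.frame if full_precision else self.rounded()
        frame.to_csv(path, index=False)
        with open(path, "a") as fh:
            fh.write("\n")
            for k, v in self.summary.items():
                if isinstance(v, float) and not full_precision:
                    v = sigfig(v, 3)
                fh.write(f"# {k},{v}\n")

    def render_text(self) -> str:
        body = self.rounded().to_string(index=False)
        lines = [self.title, body, "-" * 40] if self.title else [body, "-" * 40]
        for k, v in self.summary.items():
            if isinstance(v, float):
                v = sigfig(v, 3)
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _empty(kind: str, what: str) -> ReportTable:
    warnings.warn(f"no rows for {what}; emitting empty report", EmptyReportWarning)
    return ReportTable(kind, pd.DataFrame(columns=ROW_COLUMNS + ["pct_fs_dri"]), {})


# ---------------------------------------------------------------------------
# standard reports
# ---------------------------------------------------------------------------


def report_food(
    summaries: Iterable[ResidueSummary], food_id: str, ctx, kind: str = "3"
) -> ReportTable:
    """All analytes found in one food (report kind 3 shape).

    Summary follows the published layout: "Average Number of Samples" is the
    arithmetic mean of per-analyte N (analyte panels differ within a food),
    and residues-per-sample = total positives / average N.
    """
    subset = [s for s in summaries if s.food_id == food_id]
    df = compute_rows(subset, ctx)
    if df.empty:
        return _empty(kind, f"food {food_id!r}")
    df = _rank(df, "analyte_id")
    avg_n = df.n.mean()
    total_pos = int(df.np.sum())
    summary = {
        "average_n_samples": float(avg_n),
        "total_positives": total_pos,
        "aggregate_dri_m": float(df.dri_m.sum()),
        "aggregate_fs_dri": float(df.fs_dri.sum()),
        "residues_per_sample": total_pos / avg_n,
        "n_analytes": int(df.analyte_id.nunique()),
    }
    return ReportTable(kind, df, summary, title=f"Food report: {food_id}")


def report_pesticide(
    summaries: Iterable[ResidueSummary], analyte_id: str, ctx, kind: str = "4"
) -> ReportTable:
    """All foods in which one analyte was found (report kind 4 shape).

    Here the bottom row totals samples across foods, so residues-per-sample
    = total positives / total samples.
    """
    subset = [s for s in summaries if s.analyte_id == analyte_id]
    df = compute_rows(subset, ctx)
    if df.empty:
        return _empty(kind, f"analyte {analyte_id!r}")
    df["food_label"] = [
        f if form in ("any", "") else f"{f} ({form})"
        for f, form in zip(df.food_id, df.food_form)
    ]
    df = _rank(df, "food_label")
    total_n = int(df.n.sum())
    total_pos = int(df.np.sum())
    summary = {
        "total_samples": total_n,
        "total_positives": total_pos,
        "aggregate_dri_m": float(df.dri_m.sum()),
        "aggregate_fs_dri": float(df.fs_dri.sum()),
        "residues_per_sample": total_pos / total_n,
        "n_foods": int(df.groupby(["food_id", "food_form"]).ngroups),
    }
    return ReportTable(kind, df, summary, title=f"Pesticide report: {analyte_id}")


FOOD_ROW_COLUMNS = ["food_id", "avg_n", "positives", "residues_per_sample", "dri_m", "fs_dri"]


def _assemble_all_foods(rows: pd.DataFrame, kind: str, group_col: str = "food_id") -> ReportTable:
    df = _rank(rows, group_col)
    df["pct_dri_m"] = 100.0 * df.dri_m / df.dri_m.sum()
    n_foods = len(df)
    summary = {
        "sum_avg_n_samples": float(df.avg_n.sum()),
        "total_positives": int(df.positives.sum()),
        "aggregate_dri_m": float(df.dri_m.sum()),
        "aggregate_fs_dri": float(df.fs_dri.sum()),
        "residues_per_sample": float(df.positives.sum() / df.avg_n.sum()),
        "n_foods": n_foods,
        "avg_dri_m_per_food": float(df.dri_m.sum() / n_foods),
        "avg_fs_dri_per_food": float(df.fs_dri.sum() / n_foods),
    }
    return ReportTable(kind, df, summary, title="All foods")


def report_all_foods_from_rows(rows: pd.DataFrame, kind: str = "5") -> ReportTable:
    """Assemble the all-foods report from prebuilt per-food aggregate rows
    (columns as :data:`FOOD_ROW_COLUMNS`)."""
    return _assemble_all_foods(rows.copy(), kind)


def report_all_foods(
    summaries: Iterable[ResidueSummary], ctx, kind: str = "5", group_col: str = "food_id"
) -> ReportTable:
    """Aggregate DRI values by food across all analytes (report kind 5).

    ``group_col="food_group"`` (requires a ``food_group`` column merged into
    the rows by the caller) gives the kind-8 layout.
    """
    df = compute_rows(summaries, ctx)
    if df.empty:
        return _empty(kind, "all foods")
    per_food = (
        df.groupby(group_col if group_col in df.columns else "food_id")
        .agg(avg_n=("n", "mean"), positives=("np", "sum"), dri_m=("dri_m", "sum"), fs_dri=("fs_dri", "sum"))
        .reset_index()
    )
    per_food["residues_per_sample"] = per_food.positives / per_food.avg_n
    return _assemble_all_foods(per_food, kind, per_food.columns[0])


def report_all_pesticides_from_rows(
    rows: pd.DataFrame,
    kind: str = "6",
    top_k: int | None = None,
    others: dict | None = None,
) -> ReportTable:
    """Assemble the all-pesticides report from per-analyte aggregate rows
    (columns ``analyte_id, n, np, dri_m, fs_dri`` and optional ``family``).

    *others*, when given, supplies pre-aggregated totals for analytes not
    listed row-by-row (the printed "other pesticides" block)."""
    df = _rank(rows.copy(), "analyte_id")
    oth = dict(others or {"count": 0, "positives": 0, "dri_m": 0.0, "fs_dri": 0.0})
    if top_k is not None and top_k < len(df):
        tail = df.iloc[top_k:]
        oth = {
            "count": oth["count"] + len(tail),
            "positives": oth["positives"] + int(tail.np.sum()),
            "dri_m": oth["dri_m"] + float(tail.dri_m.sum()),
            "fs_dri": oth["fs_dri"] + float(tail.fs_dri.sum()),
        }
        df = df.iloc[:top_k].copy()
    all_dri_m = float(df.dri_m.sum()) + oth["dri_m"]
    all_fs = float(df.fs_dri.sum()) + oth["fs_dri"]
    df["pct_fs_dri"] = 100.0 * df.fs_dri / all_fs if all_fs > 0 else 0.0
    df["pct_dri_m"] = 100.0 * df.dri_m / all_dri_m if all_dri_m > 0 else 0.0
    summary = {
        "top_positives": int(df.np.sum()),
        "top_dri_m": float(df.dri_m.sum()),
        "top_fs_dri": float(df.fs_dri.sum()),
        "others_count": oth["count"],
        "others_positives": int(oth["positives"]),
        "others_dri_m": float(oth["dri_m"]),
        "others_fs_dri": float(oth["fs_dri"]),
        "total_positives": int(df.np.sum() + oth["positives"]),
        "aggregate_dri_m": all_dri_m,
        "aggregate_fs_dri": all_fs,
    }
    return ReportTable(kind, df, summary, title="All pesticides")


def report_all_pesticides(
    summaries: Iterable[ResidueSummary], ctx, kind: str = "6", top_k: int | None = None
) -> ReportTable:
    """Aggregate DRI values by analyte across all foods (report kind 6)."""
    df = compute_rows(summaries, ctx)
    if df.empty:
        return _empty(kind, "all pesticides")
    per = (
        df.groupby("analyte_id")
        .agg(n=("n", "sum"), np=("np", "sum"), dri_m=("dri_m", "sum"), fs_dri=("fs_dri", "sum"))
        .reset_index()
    )
    per["pct_positive"] = per.np / per.n
    return report_all_pesticides_from_rows(per, kind, top_k)


def report_by_type(summaries: Iterable[ResidueSummary], ctx, kind: str = "7") -> ReportTable:
    """Residue counts and aggregate DRI values by pesticide type (kind 7)."""
    df = compute_rows(summaries, ctx)
    if df.empty:
        return _empty(kind, "pesticide types")
    df["ptype"] = df.analyte_id.map(ctx.ptype)
    per = (
        df.groupby("ptype")
        .agg(residues=("np", "sum"), dri_m=("dri_m", "sum"), fs_dri=("fs_dri", "sum"))
        .reset_index()
        .rename(columns={"residues": "np"})
    )
    per = _rank(per, "ptype").rename(columns={"np": "residues"})
    summary = {
        "total_residues": int(per.residues.sum()),
        "aggregate_dri_m": float(per.dri_m.sum()),
        "aggregate_fs_dri": float(per.fs_dri.sum()),
    }
    return ReportTable(kind, per, summary, title="By pesticide type")


# ---------------------------------------------------------------------------
# stratum comparison (domestic vs imported; conventional vs organic)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumTotals:
    """Per-stratum totals used in comparison (ratio) reports."""

    label: str
    avg_samples: float  # average N per analyte
    residues: int  # total positive determinations
    pct_zero_residue: float | None  # % of samples with no positive at all
    residues_per_sample: float
    dri_m: float
    fs_dri: float


def stratum_totals(
    records: Sequence[SampleRecord], ctx, label: str, spec: SelectionSpec | None = None
) -> StratumTotals:
    """Compute one stratum's totals from raw samples."""
    if spec is not None:
        records = select(records, spec)
    summaries = summarize_samples(records)
    if spec is not None:
        summaries = apply_rule_of_10(summaries, spec)
    df = compute_rows(summaries, ctx)
    n_samples = len({r.sample_id for r in records})
    n_zero = sum(1 for r in records if not r.positives)
    avg_n = float(df.n.mean()) if not df.empty else 0.0
    residues = int(df.np.sum()) if not df.empty else 0
    return StratumTotals(
        label=label,
        avg_samples=avg_n,
        residues=residues,
        pct_zero_residue=100.0 * n_zero / n_samples if n_samples else None,
        residues_per_sample=residues / avg_n if avg_n else 0.0,
        dri_m=float(df.dri_m.sum()) if not df.empty else 0.0,
        fs_dri=float(df.fs_dri.sum()) if not df.empty else 0.0,
    )


_RATIO_FIELDS = [
    "avg_samples",
    "residues",
    "pct_zero_residue",
    "residues_per_sample",
    "dri_m",
    "fs_dri",
]


def compare_strata(a: StratumTotals, b: StratumTotals, kind: str = "comparison") -> ReportTable:
    """Two stratum rows plus their elementwise ratio row (a / b).

    A ratio element is absent (NaN, with a warning) where the denominator is
    zero or undefined.
    """
    rows = []
    for t in (a, b):
        rows.append({"stratum": t.label, **{f: getattr(t, f) for f in _RATIO_FIELDS}})
    ratio: dict = {"stratum": f"ratio {a.label}/{b.label}"}
    for f in _RATIO_FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        if va is None or vb in (None, 0) or (isinstance(vb, float) and vb == 0.0):
            warnings.warn(
                f"ratio for {f!r} undefined ({a.label}/{b.label})", EmptyReportWarning
            )
            ratio[f] = math.nan
        else:
            ratio[f] = va / vb
    frame = pd.DataFrame(rows + [ratio])
    summary = {"fs_dri_ratio": ratio["fs_dri"], "dri_m_ratio": ratio["dri_m"]}
    return ReportTable(kind, frame, summary, title=f"{a.label} vs {b.label}")


def compare_strata_records(
    records: Sequence[SampleRecord],
    axis: str,
    ctx,
    spec: SelectionSpec | None = None,
) -> ReportTable:
    """Comparison report computed from raw samples.

    ``axis="origin"`` compares domestic vs combined imports (program taken
    from the records); ``axis="claim"`` compares conventional vs organic.
    """
    base = spec or SelectionSpec()
    if axis == "claim":
        specs = [("conventional", "conventional"), ("organic", "organic")]
        pairs = [
            (lbl, SelectionSpec(base.origin_option, c, base.rule_of_10, base.include_banned_ocs))
            for lbl, c in specs
        ]
    elif axis == "origin":
        program = records[0].program if records else "us_pdp"
        dom = "domestic_us" if program == "us_pdp" else "domestic_uk"
        pairs = [
            ("domestic", SelectionSpec(dom, base.claim_option, base.rule_of_10, base.include_banned_ocs)),
            ("imported", SelectionSpec("all_imports", base.claim_option, base.rule_of_10, base.include_banned_ocs)),
        ]
    else:
        raise ValueError(f"axis must be 'origin' or 'claim', got {axis!r}")
    a = stratum_totals(records, ctx, pairs[0][0], pairs[0][1])
    b = stratum_totals(records, ctx, pairs[1][0], pairs[1][1])
    return compare_strata(a, b)


def report_filename(kind, spec: SelectionSpec, year: int, program: str = "us") -> str:
    """Deterministic output name encoding report kind and selection."""
    return f"r{int(kind):02d}_{program}_{spec.tag()}_{year}.csv"
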