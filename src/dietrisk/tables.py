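"""Published report tables as ready-made fixtures.

Each fixture transcribes one printed report table (a specific food, analyte,
year and selection) into summary inputs — N, NP, mean of positives, cRfC,
serving — from which the report builders recompute DRI-M, FS-DRI, percent
shares and the bottom-row statistics.  They exercise the full report path on
real published numbers without bundling any agency archive.

A handful of printed cRfC cells are internally inconsistent with the same
row's printed DRI-M (transcription slips in the source tables; e.g. the
1999 cucumbers row, or a cRfC printed for the wrong serving size).  The
row's DRI-M column is the system's own computed output, so it is treated as
authoritative: whenever the printed DRI-M is not the round-half-up of
mean/cRfC at the DRI-M's printed significant digits, the effective cRfC is
back-computed as mean / DRI-M.  The rule is mechanical and applied
uniformly; consistent rows keep their printed cRfC at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import pandas as pd

from .core import ResidueSummary
from .distribution import DistributionRow
from .reports import (
    CrfcTable,
    ReportTable,
    StratumTotals,
    report_all_foods_from_rows,
    report_all_pesticides_from_rows,
    report_food,
    report_pesticide,
)

__all__ = [
    "PrintedDriRow",
    "PrintedDriTable",
    "PrintedAggregateTable",
    "effective_crfc",
    "table_fixtures",
]


def _sig_digits(printed: str) -> int:
    return len(printed.lstrip("-").replace(".", "").lstrip("0"))


def _round_sig(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = n - 1 - math.floor(math.log10(abs(x)))
    return float(d.quantize(Decimal(1).scaleb(-shift), rounding=ROUND_HALF_UP))


def effective_crfc(mean_ppm: float, crfc_printed: float, dri_m_printed: str) -> float:
    """Printed cRfC, unless it contradicts the row's printed DRI-M."""
    target = float(dri_m_printed)
    if _round_sig(mean_ppm / crfc_printed, _sig_digits(dri_m_printed)) == target:
        return crfc_printed
    return mean_ppm / target


@dataclass(frozen=True)
class PrintedDriRow:
    """One printed report row: the summary inputs plus the printed DRI-M."""

    label: str  # analyte (food tables) or food (pesticide tables)
    n: int
    np: int
    mean_ppm: float
    crfc_printed: float
    dri_m_printed: str
    serv_g: float
    ptype: str = "other"

    @property
    def crfc_ppm(self) -> float:
        return effective_crfc(self.mean_ppm, self.crfc_printed, self.dri_m_printed)


@dataclass(frozen=True)
class PrintedDriTable:
    """A printed food- or pesticide-specific report."""

    name: str
    axis: str  # "food": rows are analytes; "pesticide": rows are foods
    subject: str  # the food (axis="food") or analyte (axis="pesticide")
    year: int
    rows: tuple[PrintedDriRow, ...]
    stratum: tuple[str, str] = ("all", "conventional")

    def summaries(self) -> list[ResidueSummary]:
        out = []
        for r in self.rows:
            food = self.subject if self.axis == "food" else r.label
            analyte = r.label if self.axis == "food" else self.subject
            out.append(
                ResidueSummary(
                    food_id=food,
                    food_form="any",
                    analyte_id=analyte,
                    year=self.year,
                    n_tested=r.n,
                    n_positive=r.np,
                    mean_positives_ppm=r.mean_ppm,
                    stratum=self.stratum,
                )
            )
        return out

    def crfc_table(self) -> CrfcTable:
        by_key = {}
        ptypes = {}
        for r in self.rows:
            food = self.subject if self.axis == "food" else r.label
            analyte = r.label if self.axis == "food" else self.subject
            by_key[(food, analyte)] = (r.crfc_ppm, r.serv_g)
            ptypes[analyte] = r.ptype
        return CrfcTable(by_key=by_key, ptypes=ptypes)

    def report(self) -> ReportTable:
        ctx = self.crfc_table()
        if self.axis == "food":
            return report_food(self.summaries(), self.subject, ctx)
        return report_pesticide(self.summaries(), self.subject, ctx)


@dataclass(frozen=True)
class PrintedAggregateTable:
    """A printed all-foods or all-pesticides annual accounting."""

    name: str
    axis: str  # "food" | "pesticide"
    year: int
    frame: pd.DataFrame
    top_k: int | None = None
    others: dict | None = None

    def report(self) -> ReportTable:
        if self.axis == "food":
            return report_all_foods_from_rows(self.frame)
        return report_all_pesticides_from_rows(
            self.frame, top_k=self.top_k, others=self.others
        )


# ---------------------------------------------------------------------------
# fixture data (transcribed printed inputs)
# ---------------------------------------------------------------------------

# US-grown conventional peaches, 1996 (no banned OCs, Rule of 10 imposed).
# Columns: analyte, N, NP, mean of positives, printed cRfC, printed DRI-M,
# serving (g), pesticide type.
_PEACHES_1996 = [
    ("parathion-methyl", 198, 82, 0.0562, 0.0320, "1.756", "insecticide"),
    ("iprodione", 198, 155, 0.923, 8.000, "0.115", "fungicide"),
    ("phosmet", 168, 53, 0.217, 0.960, "0.226", "insecticide"),
    ("dicloran", 198, 102, 0.394, 4.00, "0.0986", "fungicide"),
    ("carbaryl", 198, 32, 0.412, 1.600, "0.257", "insecticide"),
    ("azinphos-methyl", 198, 17, 0.0539, 0.240, "0.225", "insecticide"),
    ("fenbutatin-oxide", 155, 35, 0.137, 2.72, "0.0504", "insecticide"),
    ("propargite", 198, 43, 0.324, 6.40, "0.0507", "insecticide"),
    ("chlorpyrifos", 198, 11, 0.00809, 0.0480, "0.169", "insecticide"),
    ("dicofol-pp", 198, 2, 0.0470, 0.0640, "0.734", "insecticide"),
    ("methomyl", 198, 3, 0.183, 1.28, "0.143", "insecticide"),
    ("myclobutanil", 198, 20, 0.0548, 4.00, "0.0137", "fungicide"),
    ("diazinon", 198, 2, 0.004, 0.0320, "0.125", "insecticide"),
    ("endosulfan-sulfate", 198, 4, 0.0445, 0.960, "0.0464", "insecticide"),
    ("endosulfan-ii", 198, 5, 0.0196, 0.960, "0.0204", "insecticide"),
    ("endosulfan-i", 198, 4, 0.0105, 0.960, "0.0109", "insecticide"),
    ("captan", 198, 11, 0.0640, 20.8, "0.00308", "fungicide"),
    ("benomyl", 199, 2, 0.0830, 8.00, "0.0104", "fungicide"),
    ("thiabendazole", 198, 2, 0.0420, 5.28, "0.00796", "fungicide"),
    ("imazalil", 198, 3, 0.0170, 4.00, "0.00425", "fungicide"),
    ("permethrin-total", 198, 1, 0.480, 40.0, "0.0120", "insecticide"),
    ("dcpa", 198, 1, 0.0130, 1.60, "0.00813", "herbicide"),
    ("chlorothalonil", 198, 1, 0.0120, 3.20, "0.00375", "fungicide"),
]

# UK-grown conventional spring onions, 2016.  Serving 16.7 g (2/3 of a 25-g
# RACC).  The propamocarb cRfC is entered at 115.2 ppm — the value its
# stated cRfD of 0.12 mg/kg-bw/day implies at this serving; the table's
# printed 9.60 is a documented misprint inconsistent with its own DRI-M.
_SPRING_ONIONS_2016 = [
    ("propamocarb", 38, 1, 0.900, 115.2, "0.00781", "fungicide"),
    ("cyprodinil", 38, 3, 0.0467, 25.9, "0.00180", "fungicide"),
    ("iprodione", 38, 5, 0.034, 48.0, "0.000708", "fungicide"),
    ("fludioxonil", 38, 3, 0.030, 28.8, "0.00104", "fungicide"),
    ("azoxystrobin", 38, 10, 0.053, 173.0, "0.000307", "fungicide"),
    ("tefluthrin", 38, 1, 0.010, 4.80, "0.00208", "insecticide"),
    ("bac", 38, 5, 0.032, 96.0, "0.000333", "other"),
    ("dimethomorph", 38, 8, 0.0188, 96.0, "0.000195", "fungicide"),
    ("tebuconazole", 38, 2, 0.020, 27.8, "0.000718", "fungicide"),
    ("ddac", 38, 5, 0.026, 96.0, "0.000271", "other"),
    ("chlorothalonil", 38, 1, 0.020, 19.2, "0.00104", "fungicide"),
    ("fluopicolide", 38, 1, 0.090, 192.0, "0.000469", "fungicide"),
    ("boscalid", 38, 2, 0.040, 209.3, "0.000191", "fungicide"),
]

# Chlorpyrifos in US-grown conventional foods, 1999 (Rule of 10 imposed).
# Columns: food, N, NP, mean, printed cRfC, printed DRI-M, serving (g).
_CHLORPYRIFOS_1999 = [
    ("Apples-Single Servings", 1354, 416, 0.0374, 0.0483, "0.774", 99.0),
    ("Apples", 360, 79, 0.0207, 0.0483, "0.428", 99.0),
    ("Sweet Bell Peppers", 515, 24, 0.0815, 0.0783, "1.041", 61.0),
    ("Pears-Single Servings", 275, 2, 0.119, 0.0404, "2.93", 119.0),
    ("Pears", 279, 2, 0.0785, 0.0404, "1.94", 119.0),
    ("Tomatoes", 219, 8, 0.0133, 0.0500, "0.265", 96.0),
    ("Spinach, Frozen", 693, 47, 0.0114, 0.0923, "0.123", 52.0),
    ("Cucumbers", 377, 4, 0.0430, 0.0785, "0.496", 55.0),
    ("Strawberries", 602, 6, 0.0230, 0.0500, "0.460", 96.0),
    ("Cantaloupe", 548, 9, 0.0122, 0.0450, "0.272", 107.0),
    ("Tomatoes, Canned", 352, 6, 0.0050, 0.0595, "0.0840", 81.0),
]

# Glyphosate in UK-grown conventional foods, 2016.
_GLYPHOSATE_2016 = [
    ("Breakfast Cereal: Oats", 13, 13, 0.58, 1050.0, "0.000549", 26.7),
    ("Rye Grain", 24, 5, 0.96, 988.0, "0.000972", 28.4),
    ("Breakfast Cereal: Bran", 32, 26, 0.25, 1050.0, "0.000242", 26.7),
    ("Breakfast Cereal: Not Specified", 12, 9, 0.19, 1050.0, "0.000180", 26.7),
    ("Gluten Free: Free-from cereal", 13, 3, 0.50, 955.0, "0.000524", 29.3),
    ("Ordinary Bread: Wholemeal", 34, 12, 0.28, 933.0, "0.000304", 30.0),
    ("Ordinary Bread: Other", 20, 7, 0.17, 933.0, "0.000184", 30.0),
    ("Breakfast Cereal: Wheat", 30, 3, 0.40, 1050.0, "0.000381", 26.7),
    ("Ordinary Bread: White", 87, 8, 0.13, 724.0, "0.000134", 38.7),
    ("Specialty Bread: Pitta", 19, 1, 0.10, 741.0, "0.000135", 37.8),
]

# UK-grown and imported conventional potatoes, 2013 (two strata).
_UK_POTATOES_2013_DOMESTIC = [
    ("chlorpropham", 102, 26, 1.55, 10.7, "0.146", "growth-regulator"),
    ("maleic-hydrazide", 102, 20, 9.58, 53.3, "0.180", "growth-regulator"),
    ("fosthiazate", 102, 1, 0.020, 0.0360, "0.561", "insecticide"),
    ("thiabendazole", 102, 1, 2.00, 7.04, "0.284", "fungicide"),
    ("pencycuron", 102, 6, 0.025, 2.13, "0.0117", "fungicide"),
    ("imazalil", 102, 1, 0.300, 5.33, "0.0563", "fungicide"),
    ("propamocarb", 102, 6, 0.0233, 25.6, "0.000911", "fungicide"),
    ("azoxystrobin", 102, 1, 0.0200, 38.4, "0.000521", "fungicide"),
]
_UK_POTATOES_2013_IMPORTED = [
    ("chlorpropham", 13, 9, 0.933, 10.7, "0.0875", "growth-regulator"),
    ("maleic-hydrazide", 13, 2, 8.800, 53.3, "0.165", "growth-regulator"),
    ("thiabendazole", 13, 1, 0.600, 7.04, "0.0852", "fungicide"),
    ("imazalil", 13, 1, 0.040, 5.33, "0.00750", "fungicide"),
    ("propamocarb", 13, 1, 0.020, 25.6, "0.000781", "fungicide"),
]

# Aggregate residue/risk indicators: US potatoes 2015, domestic vs imports.
_US_POTATOES_2015 = (
    StratumTotals("domestic", 658.0, 1763, 0.152, 2.68, 3.90, 0.204),
    StratumTotals("imported", 23.0, 58, 0.0, 2.53, 0.558, 0.099),
)

# US-grown apples 2009: conventional vs organic production.
_APPLES_2009 = (
    StratumTotals("conventional", 571.0, 3522, 1.05, 6.16, 11.8, 0.223),
    StratumTotals("organic", 22.0, 34, 31.3, 1.5, 0.00328, 0.000874),
)

# Residue frequency and aggregate DRI by food: US-grown conventional, 2016.
# Columns: food, average N per analyte, total positives, DRI-M, FS-DRI.
_US_ALL_FOODS_2016 = [
    ("Spinach", 549, 4672, 4.50, 0.763),
    ("Green Beans", 363, 693, 4.78, 0.372),
    ("Cherries, Frozen", 62, 490, 1.08, 0.303),
    ("Potatoes", 651, 1769, 1.62, 0.224),
    ("Pears", 586, 2711, 1.89, 0.193),
    ("Apples", 481, 2189, 1.85, 0.160),
    ("Strawberries", 451, 3830, 2.20, 0.129),
    ("Lettuce", 707, 1676, 2.91, 0.0637),
    ("Sweet Potatoes", 508, 464, 0.624, 0.0519),
    ("Grapes", 336, 1698, 0.544, 0.0396),
    ("Tomatoes", 206, 769, 0.482, 0.0221),
    ("Cucumbers", 248, 405, 1.55, 0.0213),
    ("Oranges", 611, 1065, 0.0625, 0.0193),
    ("Apple Sauce", 166, 663, 0.107, 0.0168),
    ("Cranberries", 119, 82, 0.321, 0.0123),
    ("Grapefruit", 632, 1210, 0.0424, 0.0078),
    ("Tomatoes, Canned", 164, 190, 0.117, 0.0026),
    ("Olives, Canned", 145, 55, 0.00483, 0.00079),
    ("Cranberries, Frozen", 20, 7, 0.00550, 0.00030),
    ("Milk", 632, 18, 0.00169, 0.000048),
    ("Eggs", 271, 2, 0.000209, 0.0000015),
]

# Top 20 pesticides in UK-grown conventional samples, 2016, plus the
# pre-aggregated block for the 82 other detected pesticides.
_UK_TOP20_2016 = [
    ("pirimiphos-methyl", "organophosphate", 296, 36, 14.3, 1.76),
    ("lambda-cyhalothrin", "pyrethroid", 18, 6, 0.611, 0.319),
    ("profenofos", "organophosphate", 22, 12, 0.416, 0.227),
    ("pirimicarb", "carbamate", 218, 11, 1.28, 0.199),
    ("thiacloprid", "neonicotinoid", 81, 19, 0.329, 0.122),
    ("cyprodinil", "anilinopyrimidine", 163, 40, 0.253, 0.118),
    ("chlormequat", "quaternary ammonium", 357, 293, 0.120, 0.102),
    ("chlorpropham", "carbamate", 137, 55, 0.256, 0.0881),
    ("fludioxonil", "phenylpyrrole", 184, 45, 0.186, 0.0864),
    ("propamocarb", "carbamate", 259, 30, 0.0830, 0.0581),
    ("maleic-hydrazide", "pyridazine", 123, 33, 0.207, 0.0554),
    ("deltamethrin", "pyrethroid", 267, 15, 0.181, 0.0328),
    ("bupirimate", "pyrimidinol", 60, 24, 0.0657, 0.0322),
    ("dithiocarbamates", "disulfur compounds", 71, 17, 0.152, 0.0321),
    ("azoxystrobin", "strobilurin", 357, 63, 0.0792, 0.0312),
    ("tebuconazole", "triazole", 326, 40, 0.0750, 0.0255),
    ("chlorate", "inorganic", 131, 27, 0.0785, 0.0223),
    ("propyzamide", "benzamide", 23, 4, 0.079, 0.0196),
    ("pyraclostrobin", "strobilurin", 117, 40, 0.0452, 0.0180),
    ("iprodione", "dicarboximide", 174, 32, 0.0359, 0.0133),
]
_UK_TOP20_OTHERS = {"count": 82, "positives": 782, "dri_m": 2.13, "fs_dri": 0.191}

# Distribution of positive residue levels relative to the mean of positives
# (US domestic conventional samples; number of positive samples, %P, min,
# mean, and the 90th/95th/99th percentile concentrations in ppm).
_DISTRIBUTIONS = [
    ("Peaches", "parathion-methyl", 1996, 82, 0.253, 0.004, 0.0562, 0.11, 0.19, 0.5),
    ("Peaches", "fludioxonil", 2014, 403, 0.65, 0.0054, 0.788, 1.5, 1.9, 3.4),
    ("Potatoes", "imidacloprid", 2016, 295, 0.452, 0.002, 0.0101, 0.022, 0.033, 0.092),
    ("Potatoes", "azoxystrobin", 2016, 192, 0.294, 0.002, 0.0811, 0.27, 0.42, 0.65),
    ("Potatoes", "boscalid", 2016, 137, 0.21, 0.0025, 0.0039, 0.0074, 0.013, 0.025),
    ("Potatoes", "phorate-sulfoxide", 2016, 4, 0.006, 0.002, 0.0571, 0.12, 0.12, 0.12),
    ("Tomatoes", "methamidophos", 1996, 51, 0.383, 0.002, 0.0350, 0.079, 0.11, 0.25),
    ("Tomatoes", "endosulfan-i", 1998, 54, 0.126, 0.003, 0.00841, 0.01, 0.017, 0.095),
    ("Tomatoes", "endosulfan-ii", 1998, 62, 0.145, 0.005, 0.0125, 0.013, 0.032, 0.13),
    ("Tomatoes", "bifenthrin", 2015, 133, 0.401, 0.002, 0.00928, 0.02, 0.027, 0.048),
]


def _food_table(name, subject, year, rows, serv_g):
    return PrintedDriTable(
        name=name,
        axis="food",
        subject=subject,
        year=year,
        rows=tuple(
            PrintedDriRow(a, n, np_, mean, crfc, drim, serv_g, ptype)
            for a, n, np_, mean, crfc, drim, ptype in rows
        ),
    )


@lru_cache(maxsize=1)
def table_fixtures() -> dict:
    """All packaged printed-table fixtures, keyed by a short name."""
    fixtures: dict = {}
    fixtures["peaches_1996"] = _food_table(
        "peaches_1996", "peaches", 1996, _PEACHES_1996, 100.0
    )
    fixtures["spring_onions_2016"] = _food_table(
        "spring_onions_2016", "spring-onions", 2016, _SPRING_ONIONS_2016, 16.7
    )
    fixtures["chlorpyrifos_1999"] = PrintedDriTable(
        name="chlorpyrifos_1999",
        axis="pesticide",
        subject="chlorpyrifos",
        year=1999,
        rows=tuple(
            PrintedDriRow(f, n, np_, mean, crfc, drim, serv, "insecticide")
            for f, n, np_, mean, crfc, drim, serv in _CHLORPYRIFOS_1999
        ),
    )
    fixtures["glyphosate_2016"] = PrintedDriTable(
        name="glyphosate_2016",
        axis="pesticide",
        subject="glyphosate",
        year=2016,
        rows=tuple(
            PrintedDriRow(f, n, np_, mean, crfc, drim, serv, "herbicide")
            for f, n, np_, mean, crfc, drim, serv in _GLYPHOSATE_2016
        ),
    )
    fixtures["uk_potatoes_2013_domestic"] = _food_table(
        "uk_potatoes_2013_domestic", "potatoes", 2013, _UK_POTATOES_2013_DOMESTIC, 75.0
    )
    fixtures["uk_potatoes_2013_imported"] = _food_table(
        "uk_potatoes_2013_imported", "potatoes", 2013, _UK_POTATOES_2013_IMPORTED, 75.0
    )
    fixtures["us_potatoes_2015"] = _US_POTATOES_2015
    fixtures["apples_2009"] = _APPLES_2009
    fixtures["us_all_foods_2016"] = PrintedAggregateTable(
        name="us_all_foods_2016",
        axis="food",
        year=2016,
        frame=pd.DataFrame(
            [
                (f, n, pos, pos / n, d, fs)
                for f, n, pos, d, fs in _US_ALL_FOODS_2016
            ],
            columns=["food_id", "avg_n", "positives", "residues_per_sample", "dri_m", "fs_dri"],
        ),
    )
    fixtures["uk_top20_2016"] = PrintedAggregateTable(
        name="uk_top20_2016",
        axis="pesticide",
        year=2016,
        frame=pd.DataFrame(
            _UK_TOP20_2016,
            columns=["analyte_id", "family", "n", "np", "dri_m", "fs_dri"],
        ),
        top_k=20,
        others=dict(_UK_TOP20_OTHERS),
    )
    fixtures["residue_distributions"] = [
        DistributionRow(
            food_id=f,
            analyte_id=a,
            year=y,
            n=n,
            pct_positive=p,
            min_positive_ppm=lo,
            mean_positives_ppm=mean,
            p90_ppm=p90,
            p95_ppm=p95,
            p99_ppm=p99,
        )
        for f, a, y, n, p, lo, mean, p90, p95, p99 in _DISTRIBUTIONS
    ]
    return fixtures
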