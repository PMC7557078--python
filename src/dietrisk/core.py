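"""Core domain types and the dietary-risk arithmetic.

The Dietary Risk Index (DRI) expresses the pesticide intake from a single
serving of food as a fraction of the maximum acceptable chronic daily intake
(the EPA chronic Reference Dose, cRfD, or an equivalent cPAD/cADI).  Turning
the body-weight-based dose into a food-concentration threshold gives the
reference concentration

    cRfC = (cRfD x BW) / Serv        [ppm, i.e. mg pesticide per kg food]

from which three dimensionless ratios follow:

* ``DRI-M``   = mean-of-positives / cRfC   (average over positive samples)
* ``FS-DRI``  = DRI-M x %P                 (average over *all* samples)
* sample DRI  = concentration / cRfC       (one sample, one analyte)

All concentrations are ppm by weight (mg/kg).  A measurement counts as a
positive when its concentration is at or above the limit of quantification
(LOQ); trace values between LOD and LOQ are treated as non-detects, and
non-detects contribute to FS-DRI only through the %P factor (no LOQ/2
imputation).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DriError",
    "InvalidInputError",
    "NoPositivesError",
    "MissingThresholdError",
    "MissingServingError",
    "DataIntegrityError",
    "Diagnostics",
    "Measurement",
    "ToxicityThreshold",
    "FoodServing",
    "SampleRecord",
    "ResidueSummary",
    "DriValue",
    "DEFAULT_BODY_WEIGHT_KG",
    "child_serving_g",
    "crfc",
    "dri_m",
    "fs_dri",
    "sample_dri",
    "sample_aggregate_dri",
    "summarize_samples",
    "records_to_frame",
]

#: Body weight the published analyses are based on: a 16-kg (~4-year-old)
#: child, the 50th percentile of the CDC growth charts.
DEFAULT_BODY_WEIGHT_KG = 16.0


class DriError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(DriError, ValueError):
    """A numeric input violates its precondition (names the offending field)."""


class NoPositivesError(DriError):
    """Raised when a DRI is requested for a summary with zero positives."""


class MissingThresholdError(DriError, KeyError):
    """No toxicity threshold is on file for an analyte."""


class MissingServingError(DriError, KeyError):
    """No serving definition is on file for a food / food form."""


class DataIntegrityError(DriError):
    """Duplicate or mutually inconsistent input rows."""


@dataclass
class Diagnostics:
    """Counts of rows/measurements excluded from DRI computation."""

    missing_threshold: Counter = field(default_factory=Counter)
    missing_serving: Counter = field(default_factory=Counter)
    no_positives: int = 0

    def merge(self, other: "Diagnostics") -> None:
        self.missing_threshold.update(other.missing_threshold)
        self.missing_serving.update(other.missing_serving)
        self.no_positives += other.no_positives

    def summary(self) -> str:
        lines = []
        if self.missing_threshold:
            lines.append("analytes without thresholds (excluded):")
            for k, v in sorted(self.missing_threshold.items()):
                lines.append(f"  {k}: {v} row(s)")
        if self.missing_serving:
            lines.append("foods without servings (excluded):")
            for k, v in sorted(self.missing_serving.items()):
                lines.append(f"  {k}: {v} row(s)")
        lines.append(f"summaries with no positives (omitted): {self.no_positives}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Measurement:
    """One analyte determination on one sample (ppm by weight)."""

    analyte_id: str
    conc_ppm: float
    loq_ppm: float = 0.0
    lod_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_ppm < 0:
            raise InvalidInputError(f"conc_ppm must be >= 0, got {self.conc_ppm}")
        if self.loq_ppm < 0:
            raise InvalidInputError(f"loq_ppm must be >= 0, got {self.loq_ppm}")

    @property
    def is_positive(self) -> bool:
        """Quantifiable residue: concentration at or above the LOQ."""
        return self.conc_ppm >= self.loq_ppm and self.conc_ppm > 0


@dataclass(frozen=True)
class ToxicityThreshold:
    """Chronic intake limit and classification metadata for one analyte.

    ``crfd`` is in mg per kg body weight per day.  When an FQPA children's
    safety factor applies, the effective limit (the cPAD) is
    ``crfd / fqpa_factor``; authorities that publish a cPAD or cADI directly
    are entered with that value as ``crfd`` and ``fqpa_factor = 1``.
    """

    analyte_id: str
    crfd: float
    display_name: str = ""
    family: str = ""
    ptype: str = "other"  # insecticide | fungicide | herbicide | growth-regulator | other
    fqpa_factor: float = 1.0
    banned_oc: bool = False
    authority: str = ""

    def __post_init__(self) -> None:
        if self.crfd <= 0:
            raise InvalidInputError(f"crfd must be > 0, got {self.crfd}")
        if self.fqpa_factor < 1:
            raise InvalidInputError(
                f"fqpa_factor must be >= 1, got {self.fqpa_factor}"
            )

    @property
    def effective_limit(self) -> float:
        """cPAD when an FQPA factor applies, otherwise the cRfD."""
        return self.crfd / self.fqpa_factor


@dataclass(frozen=True)
class FoodServing:
    """Serving mass and body weight that convert a dose limit into a cRfC.

    ``racc_g`` is the general-population Reference Amount Customarily
    Consumed; the analysis serving defaults to 2/3 of the RACC for a 16-kg
    child.  Both are overridable so subpopulation-specific DRI values can be
    computed.
    """

    food_id: str
    food_form: str = "any"
    racc_g: float | None = None
    serv_g: float | None = None
    bw_kg: float = DEFAULT_BODY_WEIGHT_KG

    def __post_init__(self) -> None:
        if self.racc_g is None and self.serv_g is None:
            raise InvalidInputError(
                f"serving for {self.food_id!r}: need racc_g or serv_g"
            )
        if self.serv_g is None:
            object.__setattr__(self, "serv_g", child_serving_g(self.racc_g))
        if self.racc_g is not None and self.racc_g <= 0:
            raise InvalidInputError(f"racc_g must be > 0, got {self.racc_g}")
        if self.serv_g <= 0:
            raise InvalidInputError(f"serv_g must be > 0, got {self.serv_g}")
        if self.bw_kg <= 0:
            raise InvalidInputError(f"bw_kg must be > 0, got {self.bw_kg}")


def child_serving_g(racc_g: float) -> float:
    """Child serving: two-thirds of the general-population RACC."""
    return racc_g * 2.0 / 3.0


@dataclass
class SampleRecord:
    """One tested food sample with its per-analyte determinations."""

    sample_id: str
    food_id: str
    food_form: str
    year: int
    measurements: list[Measurement] = field(default_factory=list)
    quarter: int | None = None
    origin_country: str = ""
    origin_state: str | None = None
    origin_category: str | None = None  # domestic | eu_import | non_eu_import (UK files)
    claim: str = "none"  # organic | ipm | pesticide-free | none
    program: str = "us_pdp"  # us_pdp | uk_fsa

    def __post_init__(self) -> None:
        if self.quarter is not None and not 1 <= self.quarter <= 4:
            raise InvalidInputError(f"quarter must be 1-4, got {self.quarter}")
        seen = Counter(m.analyte_id for m in self.measurements)
        dups = [a for a, c in seen.items() if c > 1]
        if dups:
            raise DataIntegrityError(
                f"sample {self.sample_id}: duplicate analyte measurement(s) {dups}"
            )

    @property
    def positives(self) -> list[Measurement]:
        return [m for m in self.measurements if m.is_positive]


@dataclass(frozen=True)
class ResidueSummary:
    """Annual food x analyte x stratum summary: N, NP, %P, mean of positives."""

    food_id: str
    food_form: str
    analyte_id: str
    year: int
    n_tested: int
    n_positive: int
    mean_positives_ppm: float | None = None
    stratum: tuple[str, str] = ("all", "all")  # (origin option, claim option)

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_tested:
            raise InvalidInputError(
                f"need 0 <= n_positive <= n_tested, got {self.n_positive}/{self.n_tested}"
            )
        if self.n_positive > 0 and self.mean_positives_ppm is None:
            raise InvalidInputError("mean_positives_ppm required when n_positive > 0")
        if self.n_positive == 0 and self.mean_positives_ppm is not None:
            raise InvalidInputError("mean_positives_ppm must be absent when n_positive = 0")

    @property
    def pct_positive(self) -> float:
        """Fraction of tested samples with a quantifiable residue (exact NP/N)."""
        return self.n_positive / self.n_tested


@dataclass(frozen=True)
class DriValue:
    kind: str  # "DRI-M" | "FS-DRI" | "sample-DRI"
    value: float
    crfc_ppm: float
    inputs: object = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidInputError(f"DRI value must be >= 0, got {self.value}")


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def crfc(threshold: ToxicityThreshold, serving: FoodServing) -> float:
    """Reference concentration in ppm: (effective limit x BW) / serving mass.

    The serving is converted from grams to kilograms, so the result is mg of
    pesticide per kg of food, numerically equal to ppm by weight.
    """
    limit = threshold.effective_limit  # validated > 0 at construction
    return limit * serving.bw_kg / (serving.serv_g / 1000.0)


def dri_m(summary: ResidueSummary, crfc_ppm: float) -> DriValue:
    """Mean-of-positives DRI for one food-analyte-year summary."""
    if summary.n_positive == 0:
        raise NoPositivesError(
            f"{summary.food_id}/{summary.analyte_id} {summary.year}: no positives"
        )
    if crfc_ppm <= 0:
        raise InvalidInputError(f"crfc_ppm must be > 0, got {crfc_ppm}")
    return DriValue("DRI-M", summary.mean_positives_ppm / crfc_ppm, crfc_ppm, summary)


def fs_dri(summary: ResidueSummary, crfc_ppm: float) -> DriValue:
    """Food-supply DRI: DRI-M scaled by the exact positive fraction NP/N."""
    base = dri_m(summary, crfc_ppm)
    return DriValue("FS-DRI", base.value * summary.pct_positive, crfc_ppm, summary)


def sample_dri(concentration_ppm: float, crfc_ppm: float) -> DriValue:
    """Single-sample, single-analyte DRI: concentration / cRfC."""
    if concentration_ppm < 0:
        raise InvalidInputError(
            f"concentration_ppm must be >= 0, got {concentration_ppm}"
        )
    if crfc_ppm <= 0:
        raise InvalidInputError(f"crfc_ppm must be > 0, got {crfc_ppm}")
    return DriValue("sample-DRI", concentration_ppm / crfc_ppm, crfc_ppm)


def _lookup_serving(
    servings: Mapping, food_id: str, food_form: str
) -> FoodServing:
    for key in ((food_id, food_form), (food_id, "any"), food_id):
        if key in servings:
            return servings[key]
    raise MissingServingError(f"no serving for {food_id!r} ({food_form!r})")


def sample_aggregate_dri(
    sample: SampleRecord,
    thresholds: Mapping[str, ToxicityThreshold],
    servings: Mapping,
    diagnostics: Diagnostics | None = None,
) -> DriValue:
    """Aggregate DRI of one sample: sum of sample DRIs over its positives.

    Analytes lacking a threshold are skipped and counted in *diagnostics*;
    a missing serving for the sample's food is an error.
    """
    serving = _lookup_serving(servings, sample.food_id, sample.food_form)
    total = 0.0
    for m in sample.positives:
        thr = thresholds.get(m.analyte_id)
        if thr is None:
            if diagnostics is not None:
                diagnostics.missing_threshold[m.analyte_id] += 1
            continue
        total += sample_dri(m.conc_ppm, crfc(thr, serving)).value
    return DriValue("sample-DRI", total, math.nan, sample)


# ---------------------------------------------------------------------------
# summarisation
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = [
    "sample_id",
    "food_id",
    "food_form",
    "year",
    "quarter",
    "origin_country",
    "origin_state",
    "origin_category",
    "claim",
    "program",
    "analyte_id",
    "conc_ppm",
    "loq_ppm",
    "lod_ppm",
]


def records_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    """Long-format measurement table: one row per sample x analyte."""
    rows = []
    for s in samples:
        for m in s.measurements:
            rows.append(
                (
                    s.sample_id,
                    s.food_id,
                    s.food_form,
                    s.year,
                    s.quarter,
                    s.origin_country,
                    s.origin_state,
                    s.origin_category,
                    s.claim,
                    s.program,
                    m.analyte_id,
                    m.conc_ppm,
                    m.loq_ppm,
                    m.lod_ppm,
                )
            )
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def summarize_samples(
    samples: Sequence[SampleRecord],
    stratum: tuple[str, str] = ("all", "all"),
) -> list[ResidueSummary]:
    """Exact N / NP / %P / mean-of-positives per food x form x analyte x year.

    N counts every sample on which the analyte was determined, including
    non-detects (absence of a determination means "not analyzed" and does not
    enter N).  Duplicate (sample, analyte) determinations raise
    :class:`DataIntegrityError`.
    """
    frame = records_to_frame(samples)
    if frame.empty:
        return []
    dup = frame.duplicated(subset=["sample_id", "analyte_id"])
    if dup.any():
        bad = frame.loc[dup, ["sample_id", "analyte_id"]].iloc[0]
        raise DataIntegrityError(
            f"duplicate determination: sample {bad.sample_id!r} analyte {bad.analyte_id!r}"
        )
    frame = frame.assign(
        positive=(frame.conc_ppm >= frame.loq_ppm) & (frame.conc_ppm > 0)
    )
    grouped = frame.groupby(
        ["food_id", "food_form", "analyte_id", "year"], sort=True
    )
    out: list[ResidueSummary] = []
    for (food, form, analyte, year), g in grouped:
        npos = int(g.positive.sum())
        mean = float(g.loc[g.positive, "conc_ppm"].mean()) if npos else None
        out.append(
            ResidueSummary(
                food_id=food,
                food_form=form,
                analyte_id=analyte,
                year=int(year),
                n_tested=len(g),
                n_positive=npos,
                mean_positives_ppm=mean,
                stratum=stratum,
            )
        )
    return out


def with_stratum(
    summaries: Iterable[ResidueSummary], stratum: tuple[str, str]
) -> list[ResidueSummary]:
    """Relabel summaries with the selection they were computed under."""
    return [replace(s, stratum=stratum) for s in summaries]
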