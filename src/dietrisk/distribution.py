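"""Per-sample DRI distributions, top-risk listings and risk zones.

Annual means hide the right tail of residue distributions: the 99th
percentile concentration of positives routinely sits 4-11x above the mean.
This module characterises that tail (percentile-to-mean ratio rows), ranks
individual samples by aggregate DRI, classifies DRI-M values into the
three-zone risk continuum, and estimates the fraction of samples whose
aggregate DRI exceeds the regulatory level of concern (DRI = 1), the
quantity the 99.9th-percentile exposure policy constrains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .core import (
    Diagnostics,
    DriValue,
    InvalidInputError,
    NoPositivesError,
    SampleRecord,
    sample_aggregate_dri,
)

__all__ = [
    "DistributionRow",
    "RiskZone",
    "DEFAULT_ZONES",
    "LEVEL_OF_CONCERN",
    "distribution_table",
    "top_samples",
    "classify_risk",
    "exceedance_fraction",
    "aggregate_sample_dris",
]

#: Individual-sample DRI at or above this exceeds the regulatory
#: "level of concern" (one serving delivers the full acceptable daily intake).
LEVEL_OF_CONCERN = 1.0


@dataclass(frozen=True)
class DistributionRow:
    """Percentiles of positive concentrations and their ratios to the mean."""

    food_id: str
    analyte_id: str
    year: int
    n: int
    pct_positive: float | None
    min_positive_ppm: float
    mean_positives_ppm: float
    p90_ppm: float
    p95_ppm: float
    p99_ppm: float

    def __post_init__(self) -> None:
        if not self.min_positive_ppm <= self.p90_ppm <= self.p95_ppm <= self.p99_ppm:
            raise InvalidInputError(
                "percentiles must be ordered: min <= p90 <= p95 <= p99"
            )

    @property
    def r90(self) -> float:
        return self.p90_ppm / self.mean_positives_ppm

    @property
    def r95(self) -> float:
        return self.p95_ppm / self.mean_positives_ppm

    @property
    def r99(self) -> float:
        return self.p99_ppm / self.mean_positives_ppm


def distribution_table(
    samples: Sequence[SampleRecord],
    food_id: str,
    analyte_id: str,
    year: int | None = None,
) -> DistributionRow:
    """Distribution row for one food-analyte combination.

    Percentiles are computed over positive concentrations only, with linear
    interpolation between order statistics; ratios divide by the mean of the
    positives.
    """
    concs = []
    years = set()
    n = 0
    for s in samples:
        if s.food_id != food_id or (year is not None and s.year != year):
            continue
        for m in s.measurements:
            if m.analyte_id != analyte_id:
                continue
            n += 1
            years.add(s.year)
            if m.is_positive:
                concs.append(m.conc_ppm)
    if not concs:
        raise NoPositivesError(f"{food_id}/{analyte_id}: no positive samples")
    arr = np.asarray(concs, dtype=float)
    p90, p95, p99 = np.quantile(arr, [0.90, 0.95, 0.99], method="linear")
    return DistributionRow(
        food_id=food_id,
        analyte_id=analyte_id,
        year=year if year is not None else min(years),
        n=n,
        pct_positive=len(concs) / n,
        min_positive_ppm=float(arr.min()),
        mean_positives_ppm=float(arr.mean()),
        p90_ppm=float(p90),
        p95_ppm=float(p95),
        p99_ppm=float(p99),
    )


def aggregate_sample_dris(
    samples: Sequence[SampleRecord],
    thresholds: Mapping,
    servings: Mapping,
    diagnostics: Diagnostics | None = None,
) -> np.ndarray:
    """Aggregate (summed across analytes) DRI of every sample."""
    return np.array(
        [
            sample_aggregate_dri(s, thresholds, servings, diagnostics).value
            for s in samples
        ]
    )


def top_samples(
    samples: Sequence[SampleRecord],
    k: int,
    thresholds: Mapping,
    servings: Mapping,
) -> list[tuple[SampleRecord, DriValue, dict[str, float]]]:
    """The *k* samples with the highest aggregate DRI, descending.

    Each entry carries the per-analyte DRI contributions.  Requesting more
    samples than exist returns them all.
    """
    from .core import crfc, sample_dri, _lookup_serving

    scored = []
    for s in samples:
        serving = _lookup_serving(servings, s.food_id, s.food_form)
        contributions = {}
        for m in s.positives:
            thr = thresholds.get(m.analyte_id)
            if thr is None:
                continue
            contributions[m.analyte_id] = sample_dri(m.conc_ppm, crfc(thr, serving)).value
        total = DriValue("sample-DRI", sum(contributions.values()), math.nan, s)
        scored.append((s, total, contributions))
    scored.sort(key=lambda t: (-t[1].value, t[0].sample_id))
    return scored[: max(k, 0)]


# ---------------------------------------------------------------------------
# risk zones
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskZone:
    label: str  # deminimus | moderate | significant
    lower: float  # inclusive
    upper: float  # exclusive (inf for the top zone)


#: Three-zone continuum on the DRI-M scale.  The zones partition [0, inf):
#: deminimus below 0.01, possibly-significant strictly above 0.1, the
#: modest-to-moderate band in between.  A DRI-M of exactly 0.1 is assigned
#: to the moderate zone (risk "could lie above" 0.1).
DEFAULT_ZONES = (
    RiskZone("deminimus", 0.0, 0.01),
    RiskZone("moderate", 0.01, 0.1),
    RiskZone("significant", 0.1, math.inf),
)


def classify_risk(
    value: float,
    basis: str = "dri_m",
    zones: Sequence[RiskZone] = DEFAULT_ZONES,
) -> str:
    """Risk-zone label for a DRI-M value, or the level-of-concern flag for a
    single-sample DRI (``basis="sample"``: >= 1 is flagged)."""
    if value < 0:
        raise InvalidInputError(f"risk value must be >= 0, got {value}")
    if basis == "sample":
        return "level-of-concern" if value >= LEVEL_OF_CONCERN else "below-concern"
    if basis != "dri_m":
        raise InvalidInputError(f"basis must be 'dri_m' or 'sample', got {basis!r}")
    for zone in zones[:-1]:
        if value < zone.upper:
            return zone.label
    if value == zones[-2].upper:
        # the boundary with the top zone stays in the lower zone
        return zones[-2].label
    return zones[-1].label


def exceedance_fraction(
    values, threshold: float = LEVEL_OF_CONCERN, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Empirical P(aggregate sample DRI >= threshold) with a Wilson CI.

    *values* is an array of aggregate per-sample DRI values (see
    :func:`aggregate_sample_dris`).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("need at least one sample")
    k = int((arr >= threshold).sum())
    ci = binomtest(k, arr.size).proportion_ci(
        confidence_level=confidence, method="wilson"
    )
    return k / arr.size, (ci.low, ci.high)
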