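"""Synthetic residue datasets with known ground truth.

The generator emulates the statistical structure of residue-monitoring
summaries: per food x analyte x stratum, a detection probability (the %P
target) and a positive-concentration model.  Positive concentrations are
lognormal by default — monitoring data show heavy right tails, with 99th
percentiles up to ~11x the mean of positives, which is the lognormal
signature — and a fixed-list mode exists for exact tests.  Non-detects are
written as explicit zero-concentration rows carrying their LOQ so N is
unambiguous on re-ingestion.

Every run is reproducible from its seed, and :func:`generate` returns a
manifest of realised counts and closed-form distribution moments per
combination so pipeline stages can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FoodServing,
    InvalidInputError,
    Measurement,
    SampleRecord,
    ToxicityThreshold,
)

__all__ = [
    "ConcentrationModel",
    "lognormal_model",
    "fixed_model",
    "AnalytePlan",
    "SampleBlock",
    "GeneratorSpec",
    "generate",
    "default_spec",
]


@dataclass(frozen=True)
class ConcentrationModel:
    """Positive-concentration model: lognormal(mu, sigma) or a fixed list."""

    kind: str  # "lognormal" | "fixed"
    log_mean: float = 0.0  # mu of log-concentration
    log_sd: float = 1.0  # sigma of log-concentration
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "fixed"):
            raise InvalidInputError(f"unknown concentration model {self.kind!r}")
        if self.kind == "lognormal" and self.log_sd <= 0:
            raise InvalidInputError(f"log_sd must be > 0, got {self.log_sd}")
        if self.kind == "fixed" and not self.values:
            raise InvalidInputError("fixed model needs at least one value")

    @property
    def true_mean(self) -> float:
        """Closed-form mean of a positive concentration."""
        if self.kind == "fixed":
            return float(np.mean(self.values))
        return math.exp(self.log_mean + self.log_sd**2 / 2.0)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            reps = -(-size // len(self.values))  # cycle the list deterministically
            return np.tile(np.asarray(self.values, dtype=float), reps)[:size]
        return rng.lognormal(self.log_mean, self.log_sd, size)


def lognormal_model(mean_ppm: float, log_sd: float = 0.8) -> ConcentrationModel:
    """Lognormal model parameterised by its arithmetic mean of positives."""
    if mean_ppm <= 0:
        raise InvalidInputError(f"mean_ppm must be > 0, got {mean_ppm}")
    return ConcentrationModel(
        "lognormal", log_mean=math.log(mean_ppm) - log_sd**2 / 2.0, log_sd=log_sd
    )


def fixed_model(values: Sequence[float]) -> ConcentrationModel:
    return ConcentrationModel("fixed", values=tuple(float(v) for v in values))


@dataclass(frozen=True)
class AnalytePlan:
    """One analyte tested on a sample block."""

    analyte_id: str
    detect_prob: float
    model: ConcentrationModel
    loq_ppm: float = 1e-4  # small enough that lognormal draws below it are negligible

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_prob <= 1.0:
            raise InvalidInputError(
                f"detect_prob must be in [0, 1], got {self.detect_prob}"
            )


@dataclass(frozen=True)
class SampleBlock:
    """A homogeneous batch of samples: one food, year and stratum."""

    food_id: str
    n_samples: int
    analytes: tuple[AnalytePlan, ...]
    food_form: str = "any"
    year: int = 2016
    origin_country: str = "US"
    origin_category: str | None = None
    claim: str = "none"
    program: str = "us_pdp"

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise InvalidInputError(f"n_samples must be >= 0, got {self.n_samples}")


@dataclass
class GeneratorSpec:
    """Full dataset plan: foods, toxicity thresholds and sample blocks."""

    servings: dict
    thresholds: dict[str, ToxicityThreshold]
    blocks: list[SampleBlock]
    seed: int = 0


MANIFEST_COLUMNS = [
    "food_id",
    "food_form",
    "analyte_id",
    "year",
    "origin_country",
    "claim",
    "n",
    "np_realized",
    "detect_prob",
    "true_mean_ppm",
    "realized_mean_ppm",
]


def generate(spec: GeneratorSpec) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Draw the dataset; identical seeds give identical output.

    Returns the sample records and a manifest with one row per
    food x analyte x block combination holding the realised N and NP, the
    target detection probability and the true and realised means of
    positives.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    manifest_rows = []
    counter = 0
    for block in spec.blocks:
        per_sample: list[list[Measurement]] = [[] for _ in range(block.n_samples)]
        for plan in block.analytes:
            hits = rng.random(block.n_samples) < plan.detect_prob
            n_pos = int(hits.sum())
            concs = plan.model.draw(rng, n_pos)
            concs = np.maximum(concs, plan.loq_ppm)  # keep every drawn positive a positive
            it = iter(concs)
            for i in range(block.n_samples):
                conc = float(next(it)) if hits[i] else 0.0
                per_sample[i].append(
                    Measurement(plan.analyte_id, conc, plan.loq_ppm, plan.loq_ppm / 3)
                )
            realized = float(concs.mean()) if n_pos else math.nan
            manifest_rows.append(
                (
                    block.food_id,
                    block.food_form,
                    plan.analyte_id,
                    block.year,
                    block.origin_country,
                    block.claim,
                    block.n_samples,
                    n_pos,
                    plan.detect_prob,
                    plan.model.true_mean,
                    realized,
                )
            )
        for i in range(block.n_samples):
            counter += 1
            records.append(
                SampleRecord(
                    sample_id=f"S{counter:06d}",
                    food_id=block.food_id,
                    food_form=block.food_form,
                    year=block.year,
                    origin_country=block.origin_country,
                    origin_category=block.origin_category,
                    claim=block.claim,
                    program=block.program,
                    measurements=per_sample[i],
                )
            )
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return records, manifest


def default_spec(seed: int = 0, n_samples: int = 300) -> GeneratorSpec:
    """A compact, realistic monitoring year.

    Three produce items with typical panel sizes (~300 samples per food is
    the scale the US program tests), detection frequencies between 5% and
    60% and lognormal positives with log-sd 0.8 — the middle of the range
    that reproduces published 95th-percentile/mean ratios of ~2.5-4.
    """
    thresholds = {
        "methyl-parathion": ToxicityThreshold(
            "methyl-parathion", crfd=0.0002, ptype="insecticide", family="organophosphate"
        ),
        "iprodione": ToxicityThreshold(
            "iprodione", crfd=0.05, ptype="fungicide", family="dicarboximide"
        ),
        "thiabendazole": ToxicityThreshold(
            "thiabendazole", crfd=0.033, ptype="fungicide", family="benzimidazole"
        ),
        "chlorpyrifos": ToxicityThreshold(
            "chlorpyrifos", crfd=0.0003, ptype="insecticide", family="organophosphate"
        ),
        "glyphosate": ToxicityThreshold(
            "glyphosate", crfd=1.75, ptype="herbicide", family="phosphonoglycine"
        ),
    }
    servings = {
        ("peaches", "fresh"): FoodServing("peaches", "fresh", racc_g=150.0),
        ("apples", "fresh"): FoodServing("apples", "fresh", racc_g=154.0),
        ("spinach", "fresh"): FoodServing("spinach", "fresh", racc_g=85.0),
    }
    blocks = [
        SampleBlock(
            "peaches",
            n_samples,
            (
                AnalytePlan("methyl-parathion", 0.40, lognormal_model(0.056)),
                AnalytePlan("iprodione", 0.60, lognormal_model(0.9)),
                AnalytePlan("thiabendazole", 0.15, lognormal_model(0.4)),
            ),
            food_form="fresh",
        ),
        SampleBlock(
            "apples",
            n_samples,
            (
                AnalytePlan("chlorpyrifos", 0.25, lognormal_model(0.03)),
                AnalytePlan("thiabendazole", 0.55, lognormal_model(0.39)),
            ),
            food_form="fresh",
        ),
        SampleBlock(
            "spinach",
            n_samples // 3,
            (
                AnalytePlan("glyphosate", 0.05, lognormal_model(0.3)),
                AnalytePlan("chlorpyrifos", 0.10, lognormal_model(0.02)),
            ),
            food_form="fresh",
        ),
    ]
    return GeneratorSpec(servings=servings, thresholds=thresholds, blocks=blocks, seed=seed)
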