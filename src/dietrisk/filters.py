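"""Selection criteria: origin, market claim, Rule of 10, banned OCs.

A :class:`SelectionSpec` bundles the four switches that generate the report
variant matrix: country-of-origin option, market-claim option, the Rule of
10 (ignore any food x analyte x origin x claim combination with fewer than
10 tested samples), and whether detections of long-banned organochlorine
insecticides are kept.  "Conventional" means every sample whose claim is not
``organic``, so IPM and pesticide-free samples fall in the conventional set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core import (
    InvalidInputError,
    ResidueSummary,
    SampleRecord,
)

__all__ = [
    "SelectionSpec",
    "DEFAULT_BANNED_OCS",
    "ORIGIN_OPTIONS",
    "ORIGIN_OPTIONS_US",
    "ORIGIN_OPTIONS_UK",
    "CLAIM_OPTIONS",
    "select",
    "apply_rule_of_10",
    "variant_matrix",
    "total_report_count",
    "RULE_OF_10_MIN_SAMPLES",
]

#: The Rule of 10 drops combinations with fewer than this many tested
#: samples; a combination with exactly 10 is retained.
RULE_OF_10_MIN_SAMPLES = 10

#: Legacy organochlorines with essentially no remaining food uses, whose
#: occasional detections no current practice can prevent.  Endosulfan and
#: methoxychlor remain in use in some countries and are deliberately absent.
#: DDT metabolites (DDE, DDD) belong to the DDT group via the analyte map.
DEFAULT_BANNED_OCS = frozenset(
    {
        "ddt",
        "dde",
        "ddd",
        "aldrin",
        "dieldrin",
        "heptachlor",
        "heptachlor-epoxide",
        "chlordane",
        "mirex",
        "toxaphene",
    }
)

ORIGIN_OPTIONS_US = ("all", "all_imports", "imports_by_country", "domestic_us")
ORIGIN_OPTIONS_UK = (
    "all",
    "all_imports",
    "imports_by_country",
    "domestic_uk",
    "eu_imports",
    "non_eu_imports",
)
ORIGIN_OPTIONS = tuple(dict.fromkeys(ORIGIN_OPTIONS_US + ORIGIN_OPTIONS_UK))
CLAIM_OPTIONS = ("all", "conventional", "organic")


@dataclass(frozen=True)
class SelectionSpec:
    origin_option: str = "all"
    claim_option: str = "all"
    rule_of_10: bool = False
    include_banned_ocs: bool = True

    def __post_init__(self) -> None:
        if self.origin_option not in ORIGIN_OPTIONS:
            raise InvalidInputError(
                f"unknown origin option {self.origin_option!r}; "
                f"expected one of {ORIGIN_OPTIONS}"
            )
        if self.claim_option not in CLAIM_OPTIONS:
            raise InvalidInputError(
                f"unknown claim option {self.claim_option!r}; "
                f"expected one of {CLAIM_OPTIONS}"
            )

    @property
    def stratum(self) -> tuple[str, str]:
        return (self.origin_option, self.claim_option)

    def tag(self) -> str:
        """Short token used in output file names."""
        parts = [
            self.origin_option,
            self.claim_option,
            "r10" if self.rule_of_10 else "nor10",
            "withOC" if self.include_banned_ocs else "noOC",
        ]
        return "_".join(parts)


def _claim_keep(record: SampleRecord, option: str) -> bool:
    if option == "all":
        return True
    if option == "organic":
        return record.claim == "organic"
    return record.claim != "organic"  # conventional = all non-organic


def _origin_keep(record: SampleRecord, option: str) -> bool:
    if option == "all":
        return True
    if option == "domestic_us":
        return record.program == "us_pdp" and record.origin_country == "US"
    if option == "domestic_uk":
        return record.origin_country == "UK" or record.origin_category == "domestic"
    if option in ("all_imports", "imports_by_country"):
        if record.program == "uk_fsa":
            return record.origin_category in ("eu_import", "non_eu_import")
        return record.origin_country != "US"
    if option == "eu_imports":
        return record.origin_category == "eu_import"
    if option == "non_eu_imports":
        return record.origin_category == "non_eu_import"
    raise InvalidInputError(f"unknown origin option {option!r}")


def select(
    records: Sequence[SampleRecord],
    spec: SelectionSpec,
    banned_ocs: frozenset[str] | set[str] = DEFAULT_BANNED_OCS,
) -> list[SampleRecord]:
    """Apply claim and origin filters, then drop banned-OC measurements.

    Surviving records and measurements are unchanged; the output is always a
    subset.  The Rule of 10 conditions on per-combination counts and is
    applied to summaries (:func:`apply_rule_of_10`) after summarisation —
    the result is identical either way because filtering never changes N.
    """
    kept = [
        r
        for r in records
        if _claim_keep(r, spec.claim_option) and _origin_keep(r, spec.origin_option)
    ]
    if spec.include_banned_ocs:
        return kept
    out = []
    for r in kept:
        ms = [m for m in r.measurements if m.analyte_id not in banned_ocs]
        if len(ms) == len(r.measurements):
            out.append(r)
        else:
            out.append(replace(r, measurements=ms))
    return out


def apply_rule_of_10(
    summaries: Iterable[ResidueSummary], spec: SelectionSpec | None = None
) -> list[ResidueSummary]:
    """Drop food x analyte combinations with fewer than 10 tested samples.

    Granularity is the summary row itself (food x form x analyte within the
    selection's origin/claim stratum).  No-op when the spec does not request
    the rule.
    """
    if spec is not None and not spec.rule_of_10:
        return list(summaries)
    return [s for s in summaries if s.n_tested >= RULE_OF_10_MIN_SAMPLES]


def variant_matrix(program: str | None = None) -> list[SelectionSpec]:
    """Enumerate the selection variants each standard report is produced in.

    US-PDP data: 4 origin options x 3 claims x 4 inclusion combinations
    (48 variants); UK-FSA data: 6 x 3 x 4 (72).  With 8 standard report
    kinds that is 384 US + 576 UK = 960 reports.
    """
    if program is None:
        seen: dict[SelectionSpec, None] = {}
        for p in ("us_pdp", "uk_fsa"):
            for s in variant_matrix(p):
                seen[s] = None
        return list(seen)
    origins = {"us_pdp": ORIGIN_OPTIONS_US, "uk_fsa": ORIGIN_OPTIONS_UK}[program]
    return [
        SelectionSpec(o, c, rule_of_10=r10, include_banned_ocs=oc)
        for o in origins
        for c in CLAIM_OPTIONS
        for r10 in (True, False)
        for oc in (True, False)
    ]


def total_report_count(n_report_kinds: int = 8) -> int:
    """Total standard reports across both programs (960 for 8 kinds)."""
    return n_report_kinds * (
        len(variant_matrix("us_pdp")) + len(variant_matrix("uk_fsa"))
    )
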