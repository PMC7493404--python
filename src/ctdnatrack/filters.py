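"""Post-call filtering of FFPE tumor-tissue variants and tracking-set assembly.

A tissue variant seeds a subject's plasma tracking set only if it survives
four criteria: (1) it lies in a non-repetitive region, (2) it is not
predicted germline, (3) its ExAC population frequency is below 1%, and
(4) its allele frequency exceeds 5% (3% for whitelist hotspot mutations).
All four criteria are evaluated for every variant — the failure set is
complete, never short-circuited — so the per-variant report is audit-ready.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .germline import GermlineModel, featurize
from .io import AnnotationTables, VariantCall, VariantKey

__all__ = [
    "FilterOutcome",
    "TrackingSet",
    "FFPEFilterParams",
    "apply_ffpe_filters",
    "build_tracking_set",
]

CRITERIA = (
    "repetitive_region",
    "predicted_germline",
    "pop_af_ge_1pct",
    "af_below_threshold",
)


@dataclass(slots=True)
class FFPEFilterParams:
    """Thresholds of the four tissue post-call filters."""

    af_min: float = 0.05          # strict: af must be > af_min
    af_min_hotspot: float = 0.03  # strict: hotspot af must be > this
    exac_max: float = 0.01        # fail when ExAC population af >= this
    exac_db: str = "exac"

    def __post_init__(self) -> None:
        for name in ("af_min", "af_min_hotspot", "exac_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(slots=True)
class FilterOutcome:
    variant: VariantCall
    passed: bool
    failed_criteria: frozenset[str]

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed flag inconsistent with failed_criteria")


@dataclass(slots=True)
class TrackingSet:
    """The subject's tissue-confirmed somatic variants tracked in plasma."""

    subject_id: str
    variant_keys: frozenset[VariantKey]

    @property
    def n(self) -> int:
        return len(self.variant_keys)


def apply_ffpe_filters(
    variants: Iterable[VariantCall],
    annotations: AnnotationTables,
    germline_model: GermlineModel,
    params: FFPEFilterParams | None = None,
) -> list[FilterOutcome]:
    """Evaluate the four FFPE criteria on tissue variants.

    Both allele-frequency thresholds are strict (">"): af exactly at the
    threshold fails. The population-frequency criterion uses the ExAC-role
    table only, not the maximum over databases.
    """
    params = params or FFPEFilterParams()
    outcomes: list[FilterOutcome] = []
    for v in variants:
        if v.sample_type != "tissue":
            raise ValueError(
                f"FFPE filters apply to tissue variants; got {v.sample_type} "
                f"sample {v.sample_id}")
        failed: set[str] = set()
        if annotations.is_masked(v.chrom, v.pos):
            failed.add("repetitive_region")
        fv = featurize(v, annotations)
        if germline_model.predict_is_germline(fv):
            failed.add("predicted_germline")
        if annotations.pop_af(params.exac_db, v.key) >= params.exac_max:
            failed.add("pop_af_ge_1pct")
        is_hotspot = v.is_hotspot or annotations.is_hotspot(v.key)
        af_floor = params.af_min_hotspot if is_hotspot else params.af_min
        if not v.af > af_floor:
            failed.add("af_below_threshold")
        outcomes.append(FilterOutcome(
            variant=v, passed=not failed, failed_criteria=frozenset(failed)))
    return outcomes


def build_tracking_set(
    outcomes: Sequence[FilterOutcome],
    subject_id: str,
    include_synonymous: bool = True,
) -> TrackingSet:
    """Collect the deduplicated keys of passing variants into a tracking set.

    Synonymous variants are included by default; a tracking set may be
    empty (n = 0), in which case plasma detection is indeterminate.
    """
    keys = {
        o.variant.key
        for o in outcomes
        if o.passed and (include_synonymous or not o.variant.is_synonymous)
    }
    return TrackingSet(subject_id=subject_id, variant_keys=frozenset(keys))
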