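"""Longitudinal monitoring: total ctDNA quantification, molecular-progression
calling, and lead time against radiographic progression.

Total ctDNA level is expressed in mutated genome equivalents (mGE): the sum
of the detected variants' allele frequencies scaled by the number of haploid
genome equivalents in the cfDNA input (one haploid human genome weighs about
3.3 pg, i.e. 0.0033 ng). Molecular progression is called when allele
frequencies rise strictly in consecutive inter-sample steps starting from
baseline; the lead time is the gap between that call and the first
radiographic progressive-disease (PD) assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .detect import DetectionResult
from .io import SampleRecord, VariantKey

__all__ = [
    "HAPLOID_GENOME_MASS_NG",
    "TimelineSample",
    "SubjectTimeline",
    "MolecularProgressionCall",
    "total_ctdna_level",
    "detect_molecular_progression",
    "lead_time",
]

# Mass of one haploid human genome copy, in nanograms (~3.3 pg).
HAPLOID_GENOME_MASS_NG = 0.0033


@dataclass(slots=True)
class TimelineSample:
    """One plasma draw: manifest record, per-variant AFs, and derived results."""

    record: SampleRecord
    af_by_variant: dict[VariantKey, float] = field(default_factory=dict)
    detection: DetectionResult | None = None
    total_ctdna: float | None = None

    @property
    def day(self) -> int:
        return self.record.collection_day


@dataclass
class SubjectTimeline:
    """Ordered plasma samples plus clinical anchor dates for one subject.

    Diagnosis is day 0 by convention. ``recist_events`` holds (day,
    response) pairs with response in {CR, PR, SD, PD}; only the first PD is
    used downstream.
    """

    subject_id: str
    samples: list[TimelineSample]
    recist_events: list[tuple[int, str]] = field(default_factory=list)
    death_day: int | None = None
    last_imaging_day: int | None = None
    treatment_start_day: int | None = None

    def __post_init__(self) -> None:
        days = [s.day for s in self.samples]
        if days != sorted(days):
            raise ValueError(f"samples of {self.subject_id} not ordered by collection_day")
        self.recist_events = sorted(self.recist_events, key=lambda e: e[0])

    def first_pd_day(self) -> int | None:
        for day, response in self.recist_events:
            if response == "PD":
                return day
        return None


@dataclass(slots=True)
class MolecularProgressionCall:
    called: bool
    call_day: int | None = None
    supporting_variants: dict[VariantKey, list[float]] = field(default_factory=dict)


def total_ctdna_level(
    sample_afs: Mapping[VariantKey, float] | Sequence[float],
    input_mass_ng: float,
    haploid_genome_mass_ng: float = HAPLOID_GENOME_MASS_NG,
) -> float:
    """Total ctDNA level in mutated genome equivalents (mGE).

    level = (sum of detected variant AFs) x (input_mass_ng / haploid genome
    mass). Zero when no variants are detected; linear in input mass and
    additive over variants.
    """
    if input_mass_ng <= 0:
        raise ValueError(f"input_mass_ng must be positive, got {input_mass_ng}")
    afs = list(sample_afs.values()) if isinstance(sample_afs, Mapping) else list(sample_afs)
    return sum(afs) * (input_mass_ng / haploid_genome_mass_ng)


def _earliest_call_index(series: Sequence[float], k: int) -> int | None:
    """Earliest index ending a run of k consecutive strict increases whose
    starting value is at least the baseline (first-sample) value."""
    if len(series) < k + 1:
        return None
    baseline = series[0]
    run = 0
    for j in range(1, len(series)):
        run = run + 1 if series[j] > series[j - 1] else 0
        if run >= k and series[j - k] >= baseline:
            return j
    return None


def detect_molecular_progression(
    timeline: SubjectTimeline,
    k_increases: int = 2,
    rule: str = "any_variant",
    variant_keys: Sequence[VariantKey] | None = None,
) -> MolecularProgressionCall:
    """Call molecular progression from the subject's AF trajectories.

    Under ``any_variant`` (default) the call lands on the earliest sample
    day where some tracked variant's allele frequency has risen strictly in
    ``k_increases`` consecutive inter-sample steps, the run starting at a
    value no lower than that variant's baseline. Under ``mean_af`` the same
    rule is applied to the per-sample mean AF over tracked variants.
    Variants absent from a sample count as AF 0. A call needs at least
    k_increases + 1 samples.
    """
    if k_increases < 1:
        raise ValueError("k_increases must be >= 1")
    if rule not in ("any_variant", "mean_af"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(timeline.samples) < 2:
        raise ValueError("molecular progression needs >= 2 samples")
    if variant_keys is None:
        seen: dict[VariantKey, None] = {}
        for s in timeline.samples:
            for key in s.af_by_variant:
                seen.setdefault(key)
        variant_keys = list(seen)
    days = [s.day for s in timeline.samples]
    series_by_key = {
        key: [s.af_by_variant.get(key, 0.0) for s in timeline.samples]
        for key in variant_keys
    }
    if rule == "mean_af":
        if not variant_keys:
            return MolecularProgressionCall(called=False)
        mean_series = [
            sum(s.af_by_variant.get(key, 0.0) for key in variant_keys) / len(variant_keys)
            for s in timeline.samples
        ]
        j = _earliest_call_index(mean_series, k_increases)
        if j is None:
            return MolecularProgressionCall(called=False)
        return MolecularProgressionCall(
            called=True, call_day=days[j],
            supporting_variants={key: series_by_key[key][: j + 1] for key in variant_keys})

    best_j: int | None = None
    supporting: dict[VariantKey, list[float]] = {}
    for key, series in series_by_key.items():
        j = _earliest_call_index(series, k_increases)
        if j is None:
            continue
        if best_j is None or j < best_j:
            best_j, supporting = j, {key: series[: j + 1]}
        elif j == best_j:
            supporting[key] = series[: j + 1]
    if best_j is None:
        return MolecularProgressionCall(called=False)
    return MolecularProgressionCall(
        called=True, call_day=days[best_j], supporting_variants=supporting)


def lead_time(mp: MolecularProgressionCall, timeline: SubjectTimeline) -> int | None:
    """Days between the molecular-progression call and first radiographic PD.

    Positive when the molecular call precedes imaging; negative values are
    reported as-is. None when either side is missing.
    """
    if not mp.called or mp.call_day is None:
        return None
    pd_day = timeline.first_pd_day()
    if pd_day is None:
        return None
    return pd_day - mp.call_day
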