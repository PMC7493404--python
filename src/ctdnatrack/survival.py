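"""Progression-free survival by ctDNA status: Kaplan-Meier, log-rank, Cox.

PFS runs from histological diagnosis (day 0) to the first RECIST
progressive-disease event or death of any cause; subjects without either are
censored at their last imaging assessment. Estimation is delegated to
lifelines: the product-limit estimator, the two-group log-rank test, and a
univariate Cox proportional-hazards model with Efron tie handling (times are
day-resolution, so ties are common).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank

from .monitor import SubjectTimeline

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "CoxResult",
    "compute_pfs",
    "ctdna_group",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
]

CTDNA_POSITIVE = "ctDNA_positive"
CTDNA_NEGATIVE = "ctDNA_negative"


@dataclass(slots=True)
class SurvivalRecord:
    """(time, event, group, covariates) for one subject's PFS."""

    subject_id: str
    time_days: int
    event: bool
    group: str | None = None
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError(
                f"time_days must be positive, got {self.time_days} for {self.subject_id}")


@dataclass(slots=True)
class KMEstimate:
    """Product-limit survival estimate on the event-time grid."""

    times: np.ndarray            # event/censoring time grid (starts at 0)
    survival: np.ndarray         # S(t), non-increasing, S(0) = 1
    at_risk: np.ndarray          # subjects at risk entering each time
    median: float | None         # smallest t with S(t) <= 0.5, None if never

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass(slots=True)
class CoxResult:
    """Univariate Cox fit: per-level hazard ratios with Wald CIs.

    ``hazard_ratios`` maps the covariate level (or name, for a numeric
    covariate) to (HR, CI low, CI high, Wald p). ``global_p`` is the
    likelihood-ratio p over all levels of the covariate; for a binary or
    numeric covariate it coincides with the single-coefficient test.
    """

    covariate: str
    hazard_ratios: dict[str, tuple[float, float, float, float]]
    global_p: float
    n: int
    n_events: int
    converged: bool = True
    message: str = ""


def compute_pfs(timeline: SubjectTimeline) -> SurvivalRecord:
    """PFS record for one subject.

    time = min(first PD day, death day) with event=True when either exists;
    otherwise censored at the last imaging assessment.
    """
    pd_day = timeline.first_pd_day()
    death = timeline.death_day
    candidates = [d for d in (pd_day, death) if d is not None]
    if candidates:
        return SurvivalRecord(
            subject_id=timeline.subject_id, time_days=min(candidates), event=True)
    if timeline.last_imaging_day is None:
        raise ValueError(
            f"subject {timeline.subject_id}: no PD, death, or imaging record; "
            "PFS is undefined")
    return SurvivalRecord(
        subject_id=timeline.subject_id, time_days=timeline.last_imaging_day, event=False)


def ctdna_group(timeline: SubjectTimeline, which: str = "first") -> str | None:
    """ctDNA status label from the first or last post-treatment plasma sample.

    Post-treatment means collection_day strictly after the recorded
    treatment start. Indeterminate detections are skipped; returns None
    when no determinate post-treatment sample exists.
    """
    if which not in ("first", "last"):
        raise ValueError(f"which must be 'first' or 'last', got {which!r}")
    start = timeline.treatment_start_day
    if start is None:
        raise ValueError(f"subject {timeline.subject_id}: treatment start day unknown")
    post = [s for s in timeline.samples
            if s.day > start and s.detection is not None
            and s.detection.call in ("positive", "negative")]
    if not post:
        return None
    sample = post[0] if which == "first" else post[-1]
    return CTDNA_POSITIVE if sample.detection.call == "positive" else CTDNA_NEGATIVE


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate over the records."""
    if not records:
        raise ValueError("km_estimate needs >= 1 record")
    kmf = KaplanMeierFitter()
    times = [r.time_days for r in records]
    events = [r.event for r in records]
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    # median convention: smallest t with S(t) <= 0.5 (epsilon absorbs the
    # log-space round-off in the product-limit computation)
    crossed = np.nonzero(surv <= 0.5 + 1e-9)[0]
    median = float(grid[crossed[0]]) if crossed.size else None
    return KMEstimate(times=grid, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value).

    Symmetric in group order. When neither group has any event there is no
    risk-set comparison to make; (0, 1) is returned with a warning.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        warnings.warn("no events in either group; log-rank p = 1 by convention")
        return (0.0, 1.0)
    res = _lifelines_logrank(
        [r.time_days for r in group_a], [r.time_days for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return (float(res.test_statistic), float(res.p_value))


def _records_frame(records: Sequence[SurvivalRecord], covariate: str) -> pd.DataFrame:
    rows = []
    for r in records:
        if covariate == "group":
            value = r.group
        else:
            value = r.covariates.get(covariate)
        if value is None:
            continue
        rows.append({"time": r.time_days, "event": r.event, covariate: value})
    return pd.DataFrame(rows)


def cox_univariate(
    records: Sequence[SurvivalRecord],
    covariate: str = "group",
    reference: str | None = None,
) -> CoxResult:
    """Unadjusted Cox proportional-hazards model for one covariate.

    Numeric covariates enter linearly. Categorical covariates are dummy
    coded against ``reference`` (default: lexicographically first level;
    for the ctDNA ``group`` covariate the negative group is the reference)
    with per-level hazard ratios and a global likelihood-ratio p-value.
    Non-convergence or complete separation yields a flagged result rather
    than silent numbers.
    """
    df = _records_frame(records, covariate)
    if df.empty or df["event"].sum() == 0:
        raise ValueError(f"covariate {covariate!r}: no usable records or no events")
    values = df[covariate]
    numeric = pd.api.types.is_numeric_dtype(values) and values.nunique() > 2
    if values.nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant across subjects")

    if numeric:
        model_df = df.rename(columns={covariate: "x"})[["time", "event", "x"]]
        level_names = [covariate]
    else:
        levels = sorted(values.astype(str).unique())
        if reference is None:
            reference = CTDNA_NEGATIVE if covariate == "group" and CTDNA_NEGATIVE in levels \
                else levels[0]
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not among {levels}")
        other = [lv for lv in levels if lv != reference]
        model_df = pd.DataFrame({"time": df["time"], "event": df["event"]})
        for lv in other:
            model_df[f"x_{lv}"] = (values.astype(str) == lv).astype(float)
        level_names = other

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model_df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        return CoxResult(
            covariate=covariate, hazard_ratios={}, global_p=float("nan"),
            n=len(model_df), n_events=int(df["event"].sum()),
            converged=False, message=str(exc))

    summary = cph.summary
    hrs: dict[str, tuple[float, float, float, float]] = {}
    for name, row_name in zip(level_names, summary.index):
        row = summary.loc[row_name]
        hrs[name] = (
            float(row["exp(coef)"]),
            float(row["exp(coef) lower 95%"]),
            float(row["exp(coef) upper 95%"]),
            float(row["p"]),
        )
    global_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxResult(
        covariate=covariate, hazard_ratios=hrs, global_p=global_p,
        n=len(model_df), n_events=int(df["event"].sum()))
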