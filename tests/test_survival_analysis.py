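import numpy as np
import pytest

from ctdnatrack.detect import DetectionResult
from ctdnatrack.io import SampleRecord
from ctdnatrack.monitor import SubjectTimeline, TimelineSample
from ctdnatrack.survival import (
    CTDNA_NEGATIVE,
    CTDNA_POSITIVE,
    SurvivalRecord,
    compute_pfs,
    cox_univariate,
    ctdna_group,
    km_estimate,
    logrank_test,
)


def rec(subject_id, time, event, group=None, **cov):
    return SurvivalRecord(subject_id=subject_id, time_days=time, event=event,
                          group=group, covariates=cov)


def timeline(subject_id="S1", recist=(), death=None, last_imaging=None,
             treatment_start=1, sample_calls=()):
    samples = []
    for i, (day, call) in enumerate(sample_calls):
        record = SampleRecord(subject_id, f"{subject_id}-P{i:02d}", "plasma", day, 20.0)
        detection = DetectionResult(
            sample_id=record.sample_id, observed_mean_af=0.0,
            empirical_p=0.001 if call == "positive" else (None if call == "indeterminate" else 0.5),
            iterations=1000, n_used=0 if call == "indeterminate" else 5, call=call)
        samples.append(TimelineSample(record=record, detection=detection))
    return SubjectTimeline(subject_id=subject_id, samples=samples,
                           recist_events=list(recist), death_day=death,
                           last_imaging_day=last_imaging,
                           treatment_start_day=treatment_start)


class TestComputePFS:
    def test_pd_event(self):
        r = compute_pfs(timeline(recist=[(63, "SD"), (159, "PD")], last_imaging=159))
        assert (r.time_days, r.event) == (159, True)

    def test_censored_at_last_imaging(self):
        r = compute_pfs(timeline(recist=[(100, "SD")], last_imaging=200))
        assert (r.time_days, r.event) == (200, False)

    def test_death_before_pd_is_event(self):
        r = compute_pfs(timeline(recist=[(63, "SD")], death=120, last_imaging=63))
        assert (r.time_days, r.event) == (120, True)

    def test_death_after_pd_takes_earlier_day(self):
        r = compute_pfs(timeline(recist=[(90, "PD")], death=150, last_imaging=90))
        assert (r.time_days, r.event) == (90, True)

    def test_no_anchor_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_pfs(timeline())


class TestCtdnaGroup:
    def test_first_and_last_post_treatment_sample(self):
        tl = timeline(sample_calls=[(0, "positive"), (21, "negative"),
                                    (42, "positive")])
        # day-0 sample is pre-treatment (treatment starts day 1)
        assert ctdna_group(tl, "first") == CTDNA_NEGATIVE
        assert ctdna_group(tl, "last") == CTDNA_POSITIVE

    def test_indeterminate_samples_skipped(self):
        tl = timeline(sample_calls=[(21, "indeterminate"), (42, "negative")])
        assert ctdna_group(tl, "first") == CTDNA_NEGATIVE

    def test_no_determinate_post_treatment_sample_gives_none(self):
        tl = timeline(sample_calls=[(0, "positive"), (21, "indeterminate")])
        assert ctdna_group(tl, "first") is None


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor_function(self):
        times = [30, 60, 90, 120, 150, 180, 210, 240]
        records = [rec(f"S{i}", t, True) for i, t in enumerate(times)]
        km = km_estimate(records)
        n = len(times)
        for i, t in enumerate(sorted(times)):
            assert km.survival_at(t) == pytest.approx(1 - (i + 1) / n)
        # median: smallest t with S(t) <= 0.5 -> 4th order statistic
        assert km.median == 120

    def test_all_censored_curve_stays_at_one(self):
        records = [rec(f"S{i}", t, False) for i, t in enumerate([50, 100, 150])]
        km = km_estimate(records)
        assert np.all(km.survival == 1.0)
        assert km.median is None

    def test_single_event_drops_to_zero(self):
        km = km_estimate([rec("S1", 77, True)])
        assert km.survival_at(76) == 1.0
        assert km.survival_at(77) == 0.0
        assert km.median == 77

    def test_curve_monotone_within_unit_interval(self):
        rng = np.random.default_rng(1)
        records = [rec(f"S{i}", int(t) + 1, bool(e))
                   for i, (t, e) in enumerate(zip(rng.exponential(100, 40),
                                                  rng.random(40) < 0.7))]
        km = km_estimate(records)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((0 <= km.survival) & (km.survival <= 1))
        assert km.survival[0] == 1.0


def brute_force_logrank(group_a, group_b):
    """Independent oracle: observed-minus-expected over the risk sets at each
    event time, with the hypergeometric variance."""
    all_records = [(r.time_days, r.event, 0) for r in group_a] + \
                  [(r.time_days, r.event, 1) for r in group_b]
    event_times = sorted({t for t, e, _ in all_records if e})
    O_minus_E, V = 0.0, 0.0
    for t in event_times:
        at_risk = [(rt, e, g) for rt, e, g in all_records if rt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for rt, e, _ in at_risk if rt == t and e)
        d_a = sum(1 for rt, e, g in at_risk if rt == t and e and g == 0)
        O_minus_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = O_minus_E**2 / V if V > 0 else 0.0
    return chi2


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        group = [rec(f"S{i}", t, True) for i, t in enumerate([30, 60, 90])]
        clone = [rec(f"T{i}", t, True) for i, t in enumerate([30, 60, 90])]
        chi2, p = logrank_test(group, clone)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        a = [rec(f"A{i}", t, e) for i, (t, e) in
             enumerate([(30, True), (60, True), (90, False)])]
        b = [rec(f"B{i}", t, e) for i, (t, e) in
             enumerate([(45, True), (120, True), (150, False)])]
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_matches_hand_computed_risk_set_statistic(self):
        rng = np.random.default_rng(9)
        a = [rec(f"A{i}", int(t) + 1, bool(rng.random() < 0.8))
             for i, t in enumerate(rng.exponential(80, 25))]
        b = [rec(f"B{i}", int(t) + 1, bool(rng.random() < 0.8))
             for i, t in enumerate(rng.exponential(40, 25))]
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(brute_force_logrank(a, b), rel=1e-6)

    def test_no_events_conventional_p_one(self):
        a = [rec("A1", 50, False)]
        b = [rec("B1", 70, False)]
        with pytest.warns(UserWarning, match="convention"):
            chi2, p = logrank_test(a, b)
        assert (chi2, p) == (0.0, 1.0)

    def test_type_i_error_near_nominal_under_equal_hazards(self):
        """Under a true hazard ratio of 1 the log-rank test at the 0.05 level
        rejects in ~5% of replicates (3 s.e. binomial band, 500 replicates)."""
        rng = np.random.default_rng(2025)
        reps, rejections = 500, 0
        for _ in range(reps):
            times_a = rng.exponential(200, 30)
            times_b = rng.exponential(200, 30)
            cens = rng.exponential(400, 60)
            a = [rec(f"A{i}", int(min(t, c)) + 1, bool(t <= c))
                 for i, (t, c) in enumerate(zip(times_a, cens[:30]))]
            b = [rec(f"B{i}", int(min(t, c)) + 1, bool(t <= c))
                 for i, (t, c) in enumerate(zip(times_b, cens[30:]))]
            _, p = logrank_test(a, b)
            rejections += p < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se


class TestCoxUnivariate:
    @staticmethod
    def simulate_records(rng, n=71, hr=2.3, p_exposed=0.6, censoring=0.35):
        lam0 = np.log(2) / 270
        records = []
        for i in range(n):
            exposed = rng.random() < p_exposed
            lam = lam0 * (hr if exposed else 1.0)
            t = rng.exponential(1 / lam)
            c = rng.exponential((1 - censoring) / (censoring * lam))
            records.append(rec(
                f"S{i}", int(min(t, c)) + 1, bool(t <= c),
                group=CTDNA_POSITIVE if exposed else CTDNA_NEGATIVE))
        return records

    def test_recovers_binary_hazard_ratio(self):
        rng = np.random.default_rng(6)
        records = self.simulate_records(rng, n=600)
        result = cox_univariate(records, "group")
        hr, lo, hi, p = result.hazard_ratios[CTDNA_POSITIVE]
        assert lo < 2.3 < hi
        assert hr == pytest.approx(2.3, rel=0.25)
        assert result.converged

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(8)
        records = self.simulate_records(rng, n=200)
        hr_fwd = cox_univariate(records, "group")
        swapped = [rec(r.subject_id, r.time_days, r.event,
                       group=CTDNA_NEGATIVE if r.group == CTDNA_POSITIVE
                       else CTDNA_POSITIVE)
                   for r in records]
        hr_rev = cox_univariate(swapped, "group", reference=CTDNA_NEGATIVE)
        assert hr_rev.hazard_ratios[CTDNA_POSITIVE][0] == pytest.approx(
            1 / hr_fwd.hazard_ratios[CTDNA_POSITIVE][0], rel=1e-6)

    def test_constant_covariate_rejected(self):
        records = [rec(f"S{i}", 50 + i, True, group=CTDNA_POSITIVE)
                   for i in range(10)]
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(records, "group")

    def test_categorical_covariate_reports_per_level_hrs_and_global_p(self):
        rng = np.random.default_rng(10)
        records = []
        for i in range(150):
            stage = rng.choice(["IIIA", "IIIB", "IV"], p=[0.1, 0.2, 0.7])
            lam = np.log(2) / 270 * {"IIIA": 1.0, "IIIB": 1.2, "IV": 1.5}[stage]
            t = rng.exponential(1 / lam)
            records.append(rec(f"S{i}", int(t) + 1, True, stage=str(stage)))
        result = cox_univariate(records, "stage", reference="IV")
        assert set(result.hazard_ratios) == {"IIIA", "IIIB"}
        assert 0 <= result.global_p <= 1

    def test_complete_separation_flagged_not_silent(self):
        records = [rec(f"A{i}", 10 + i, True, group=CTDNA_POSITIVE) for i in range(8)]
        records += [rec(f"B{i}", 500 + i, True, group=CTDNA_NEGATIVE) for i in range(8)]
        result = cox_univariate(records, "group")
        # monotone likelihood: either flagged, or the CI is effectively unbounded
        if result.converged:
            _, lo, hi, _ = result.hazard_ratios[CTDNA_POSITIVE]
            assert hi > 1e3 or lo == 0.0
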