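import math

import numpy as np
import pytest

from ctdnatrack.detect import (
    BackgroundModel,
    classify_sample,
    detect_sample,
    enumerate_tail,
    exhaustive_pvalue,
    extract_background,
    monte_carlo_pvalue,
    observed_mean_af,
)
from ctdnatrack.filters import TrackingSet

from conftest import make_variant


def background_of(afs, sample_id="S1-P00"):
    return BackgroundModel(
        sample_id=sample_id,
        alterations=[(("chr1", 1000 + 3 * i, "A", "C"), af) for i, af in enumerate(afs)])


def tracking_of(*keys):
    return TrackingSet(subject_id="S1", variant_keys=frozenset(keys))


class TestExtractBackground:
    def test_all_tracked_gives_empty_background(self):
        variants = [make_variant(chrom="chr2", pos=p, af=0.01,
                                 sample_type="plasma", sample_id="S1-P00")
                    for p in (10, 20)]
        tracking = tracking_of(*(v.key for v in variants))
        assert extract_background(variants, tracking).size == 0

    def test_tracked_keys_never_leak_into_null(self):
        variants = [make_variant(chrom="chr2", pos=p, af=0.001,
                                 sample_type="plasma", sample_id="S1-P00")
                    for p in range(1, 1001)]
        tracked = {variants[i].key for i in (0, 100, 200, 300, 400)}
        bg = extract_background(variants, tracking_of(*tracked))
        assert bg.size == 995
        assert not ({k for k, _ in bg.alterations} & tracked)


class TestObservedMeanAF:
    def test_mean_over_observed_tracked_variants(self):
        variants = [
            make_variant(chrom="chr2", pos=10, af=0.01, depth=10000,
                         sample_type="plasma", sample_id="S1-P00"),
            make_variant(chrom="chr2", pos=20, af=0.03, depth=10000,
                         sample_type="plasma", sample_id="S1-P00"),
        ]
        mean, n = observed_mean_af(variants, tracking_of(*(v.key for v in variants)))
        assert mean == pytest.approx(0.02)
        assert n == 2

    def test_absent_tracked_variant_counts_as_zero(self):
        v = make_variant(chrom="chr2", pos=10, af=0.04, depth=10000,
                         sample_type="plasma", sample_id="S1-P00")
        tracking = tracking_of(v.key, ("chr2", 20, "A", "C"))
        mean, n = observed_mean_af([v], tracking)
        assert mean == pytest.approx(0.02)
        assert n == 2

    def test_empty_tracking_set_is_indeterminate_signal(self):
        mean, n = observed_mean_af([], tracking_of())
        assert n == 0
        assert math.isnan(mean)


class TestExhaustivePvalue:
    def test_single_element_below_observed(self):
        assert exhaustive_pvalue(0.005, 1, background_of([0.01])) == 1.0

    def test_tie_counts_toward_tail(self):
        assert exhaustive_pvalue(0.0, 1, background_of([0.0])) == 1.0

    def test_hand_enumerated_pairs(self):
        # C(4,2)=6 pair means of {1,2,3,4}e-3: {1.5,2,2.5,2.5,3,3.5}e-3;
        # means >= 0.0035 -> 1 subset -> p = (1+1)/(1+6)
        bg = background_of([0.001, 0.002, 0.003, 0.004])
        assert exhaustive_pvalue(0.0035, 2, bg) == pytest.approx(2 / 7)

    def test_cap_refused(self):
        bg = background_of(list(np.linspace(0.001, 0.01, 200)))
        with pytest.raises(ValueError, match="cap"):
            exhaustive_pvalue(0.005, 8, bg)


class TestMonteCarloPvalue:
    def test_observed_above_all_background_gives_smallest_p(self):
        bg = background_of([0.001] * 50)
        p = monte_carlo_pvalue(0.5, 3, bg, iterations=1000, seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_zero_observed_mean_gives_p_one(self):
        bg = background_of([0.001, 0.002, 0.005] * 10)
        assert monte_carlo_pvalue(0.0, 2, bg, iterations=500, seed=1) == 1.0

    def test_matches_enumeration_within_monte_carlo_error(self):
        """On the C(4,2)=6 instance the Monte Carlo p agrees with the value
        implied by full enumeration: both smooth by +1/+1, so the expected MC
        p is (1 + iterations*k/total) / (iterations + 1)."""
        bg = background_of([0.001, 0.002, 0.003, 0.004])
        k, total = enumerate_tail(0.0035, 2, bg)
        assert (k, total) == (1, 6)  # only {0.003, 0.004} has mean >= 0.0035
        t = k / total
        iters = 20_000
        p = monte_carlo_pvalue(0.0035, 2, bg, iterations=iters, seed=7)
        expected = (1 + iters * t) / (iters + 1)
        se = math.sqrt(t * (1 - t) / iters)
        assert abs(p - expected) < 3 * se

    def test_deterministic_given_seed(self):
        bg = background_of(list(np.linspace(1e-4, 5e-3, 100)))
        args = (0.002, 5, bg, 2000)
        assert monte_carlo_pvalue(*args, seed=42) == monte_carlo_pvalue(*args, seed=42)

    def test_monotone_nonincreasing_in_observed_mean(self):
        bg = background_of(list(np.linspace(1e-4, 5e-3, 120)))
        ps = [monte_carlo_pvalue(m, 4, bg, iterations=3000, seed=11)
              for m in np.linspace(0.0, 0.006, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_background_smaller_than_n_rejected(self):
        bg = background_of([0.001, 0.002])
        with pytest.raises(ValueError, match="indeterminate"):
            monte_carlo_pvalue(0.001, 3, bg, iterations=100, seed=1)
        # optional fallback: sampling with replacement
        p = monte_carlo_pvalue(0.001, 3, bg, iterations=100, seed=1,
                               with_replacement=True)
        assert 0 < p <= 1

    def test_both_sampling_paths_are_valid_without_replacement_schemes(self):
        """The rejection path (small n/m) and the top-k path (large n/m)
        both reproduce the enumerated tail fraction within Monte Carlo error."""
        rng = np.random.default_rng(5)
        afs = rng.uniform(1e-4, 5e-3, size=12).tolist()
        bg = background_of(afs)
        iters = 30_000
        for n in (1, 6):  # n=1 -> rejection; n=6 of 12 -> top-k
            k, total = enumerate_tail(0.002, n, bg)
            t = k / total
            p = monte_carlo_pvalue(0.002, n, bg, iterations=iters, seed=3)
            expected = (1 + iters * t) / (iters + 1)
            se = math.sqrt(t * (1 - t) / iters)
            assert abs(p - expected) < 4 * se


class TestClassifySample:
    def test_positive_below_alpha(self):
        r = classify_sample("s", 0.01, 5, empirical_p=0.005, iterations=1000)
        assert r.call == "positive"

    def test_exactly_alpha_is_negative(self):
        r = classify_sample("s", 0.01, 5, empirical_p=0.01, iterations=1000)
        assert r.call == "negative"

    def test_zero_tracked_variants_indeterminate(self):
        r = classify_sample("s", float("nan"), 0, empirical_p=None, iterations=1000)
        assert r.call == "indeterminate"

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            classify_sample("s", 0.01, 5, empirical_p=0.5, iterations=10, alpha=1.5)


class TestDetectSample:
    def test_end_to_end_positive_call(self):
        rng = np.random.default_rng(0)
        variants = [make_variant(chrom="chr2", pos=3 * i + 3, af=0.0005,
                                 depth=2000, sample_type="plasma",
                                 sample_id="S1-P00")
                    for i in range(300)]
        tracked = [make_variant(chrom="chr3", pos=3 * i + 3, af=0.05, depth=2000,
                                sample_type="plasma", sample_id="S1-P00")
                   for i in range(5)]
        tracking = tracking_of(*(v.key for v in tracked))
        result = detect_sample(variants + tracked, tracking, iterations=2000, seed=1)
        assert result.call == "positive"
        assert result.n_used == 5
        assert result.empirical_p == pytest.approx(1 / 2001)

    def test_indeterminate_when_background_smaller_than_tracking(self):
        tracked = [make_variant(chrom="chr3", pos=3 * i + 3, af=0.05, depth=2000,
                                sample_type="plasma", sample_id="S1-P00")
                   for i in range(5)]
        tracking = tracking_of(*(v.key for v in tracked))
        result = detect_sample(tracked, tracking, iterations=100, seed=1)
        assert result.call == "indeterminate"


def test_null_calibration_positive_rate_does_not_exceed_alpha():
    """Tracked AFs drawn from the background pool itself: empirical p is
    approximately uniform and the positive rate at alpha=0.01 shows no
    significant excess (one-sided binomial check at the 0.05 level)."""
    from scipy import stats

    rng = np.random.default_rng(2024)
    n, n_samples, iterations = 6, 400, 2000
    positives = 0
    pvals = []
    for _ in range(n_samples):
        # one shared error-AF superpopulation for background and tracked
        pool = rng.gamma(2.0, 2e-4, size=300)
        tracked_afs = rng.choice(pool, size=n, replace=False)
        bg = background_of(pool.tolist())
        p = monte_carlo_pvalue(float(tracked_afs.mean()), n, bg,
                               iterations=iterations, seed=rng)
        pvals.append(p)
        positives += p < 0.01
    binom_p = stats.binomtest(positives, n_samples, 0.01, alternative="greater").pvalue
    assert binom_p > 0.05
    # uniformity on the bulk of the distribution
    assert 0.35 < np.mean(np.asarray(pvals) <= 0.5) < 0.65


def test_power_increases_with_tumor_fraction():
    """Positive-call rate rises monotonically over a tumor-fraction grid."""
    rng = np.random.default_rng(7)
    n, reps, iterations = 6, 60, 1000
    clonal = 0.4
    rates = []
    for tf in (0.0, 0.002, 0.01, 0.05):
        hits = 0
        for _ in range(reps):
            bg_pool = rng.gamma(2.0, 2e-4, size=300)
            tracked = rng.binomial(2779, clonal * tf + 1e-4, size=n) / 2779
            p = monte_carlo_pvalue(float(tracked.mean()), n,
                                   background_of(bg_pool.tolist()),
                                   iterations=iterations, seed=rng)
            hits += p < 0.01
        rates.append(hits / reps)
    assert all(a <= b + 0.05 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.9
    assert rates[0] <= 0.05
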