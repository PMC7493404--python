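"""Monte Carlo ctDNA-presence test per plasma sample.

The observed statistic is the mean allele frequency of the subject's n
tracked (tissue-confirmed somatic) variants in the plasma sample, with
tracked variants absent from the sample contributing zero. The null is
built from the same sample's background allele alterations — non-tracked
positions with nonzero alternate reads, dominated by sequencing error. Each
Monte Carlo iteration draws n distinct background alterations and records
their mean allele frequency; the empirical p-value is the (add-one
smoothed) fraction of iteration means at or above the observed mean. A
sample is called ctDNA-positive when p < alpha (default 0.01, strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .filters import TrackingSet
from .io import VariantCall, VariantKey

__all__ = [
    "BackgroundModel",
    "DetectionResult",
    "extract_background",
    "observed_mean_af",
    "monte_carlo_pvalue",
    "enumerate_tail",
    "exhaustive_pvalue",
    "classify_sample",
    "detect_sample",
]

DEFAULT_ITERATIONS = 10_000
DEFAULT_ALPHA = 0.01
_ENUMERATION_CAP = 1_000_000


@dataclass(slots=True)
class BackgroundModel:
    """Background allele alterations of one plasma sample (the null pool)."""

    sample_id: str
    alterations: list[tuple[VariantKey, float]]

    @property
    def size(self) -> int:
        return len(self.alterations)

    def afs(self) -> np.ndarray:
        return np.array([af for _, af in self.alterations], dtype=float)


@dataclass(slots=True)
class DetectionResult:
    sample_id: str
    observed_mean_af: float
    empirical_p: float | None
    iterations: int
    n_used: int
    call: str  # "positive" | "negative" | "indeterminate"
    seed: int | None = None


def extract_background(
    plasma_variants: Iterable[VariantCall],
    tracking: TrackingSet,
) -> BackgroundModel:
    """Collect the sample's alterations at non-tracked keys.

    Tracked keys never leak into the null pool.
    """
    alterations: list[tuple[VariantKey, float]] = []
    sample_id = ""
    for v in plasma_variants:
        sample_id = sample_id or v.sample_id
        if v.key not in tracking.variant_keys:
            alterations.append((v.key, v.af))
    return BackgroundModel(sample_id=sample_id, alterations=alterations)


def observed_mean_af(
    plasma_variants: Iterable[VariantCall],
    tracking: TrackingSet,
) -> tuple[float, int]:
    """Mean allele frequency over the tracking set in this sample.

    Every tracked key counts: a tracked variant not observed in the sample
    contributes af = 0, so n stays fixed at the tracking-set size. With an
    empty tracking set the mean is undefined and (nan, 0) is returned,
    which downstream classifies as indeterminate.
    """
    if tracking.n == 0:
        return (float("nan"), 0)
    af_by_key = {v.key: v.af for v in plasma_variants}
    total = sum(af_by_key.get(key, 0.0) for key in tracking.variant_keys)
    return (total / tracking.n, tracking.n)


def _sample_means_without_replacement(
    afs: np.ndarray, n: int, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of `iterations` draws of n distinct elements of afs.

    For n much smaller than the pool, draws index tuples by rejection
    (resampling rows containing a duplicate); otherwise selects the n
    smallest of per-row uniforms, which is an exact without-replacement
    scheme. Both are deterministic given the generator state.
    """
    m = afs.size
    if n == m:
        return np.full(iterations, afs.mean())
    if n <= max(1, m // 10):
        idx = rng.integers(0, m, size=(iterations, n))
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, m, size=(int(bad.sum()), n))
        return afs[idx].mean(axis=1)
    u = rng.random((iterations, m))
    idx = np.argpartition(u, n - 1, axis=1)[:, :n]
    return afs[idx].mean(axis=1)


def monte_carlo_pvalue(
    mean_obs: float,
    n: int,
    background: BackgroundModel,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
    with_replacement: bool = False,
) -> float:
    """Empirical p-value of the observed tracked-variant mean AF.

    p = (1 + #{iteration means >= mean_obs}) / (iterations + 1); ties count
    toward the tail and the add-one smoothing keeps p strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if background.size < n and not with_replacement:
        raise ValueError(
            f"background pool ({background.size}) smaller than tracking set ({n}); "
            "detection is indeterminate (or enable with_replacement)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    afs = background.afs()
    if with_replacement and background.size < n:
        idx = rng.integers(0, afs.size, size=(iterations, n))
        means = afs[idx].mean(axis=1)
    else:
        means = _sample_means_without_replacement(afs, n, iterations, rng)
    k = int((means >= mean_obs).sum())
    return (1 + k) / (iterations + 1)


def enumerate_tail(mean_obs: float, n: int, background: BackgroundModel) -> tuple[int, int]:
    """(#subsets with mean >= mean_obs, #subsets) over every n-subset of the
    background, with the same tie semantics as the Monte Carlo test.
    Refuses above a combination cap."""
    m = background.size
    if n < 1 or m < n:
        raise ValueError("need 1 <= n <= background.size")
    total = math.comb(m, n)
    if total > _ENUMERATION_CAP:
        raise ValueError(f"C({m},{n}) = {total} exceeds enumeration cap")
    afs = background.afs()
    sums = np.array([afs[list(combo)].sum() for combo in combinations(range(m), n)])
    k = int((sums / n >= mean_obs).sum())
    return k, total


def exhaustive_pvalue(mean_obs: float, n: int, background: BackgroundModel) -> float:
    """Exact analogue of the Monte Carlo p by enumerating every n-subset.

    Uses the same tie semantics and (1+k)/(1+N) smoothing, with N the number
    of subsets. Test oracle: the Monte Carlo p converges to the enumerated
    tail fraction k/N, so the two agree within Monte Carlo error whenever the
    subset count is large enough that the smoothing terms are negligible.
    """
    k, total = enumerate_tail(mean_obs, n, background)
    return (1 + k) / (1 + total)


def classify_sample(
    sample_id: str,
    mean_obs: float,
    n_used: int,
    empirical_p: float | None,
    iterations: int,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> DetectionResult:
    """Turn a p-value into a ctDNA presence call.

    positive iff p < alpha (strict); indeterminate (n_used = 0 or no p)
    is propagated, never coerced to negative.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_used == 0 or empirical_p is None:
        call = "indeterminate"
    elif empirical_p < alpha:
        call = "positive"
    else:
        call = "negative"
    return DetectionResult(
        sample_id=sample_id,
        observed_mean_af=mean_obs,
        empirical_p=empirical_p,
        iterations=iterations,
        n_used=n_used,
        call=call,
        seed=seed,
    )


def detect_sample(
    plasma_variants: Sequence[VariantCall],
    tracking: TrackingSet,
    iterations: int = DEFAULT_ITERATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
) -> DetectionResult:
    """End-to-end presence test for one plasma sample."""
    sample_id = plasma_variants[0].sample_id if plasma_variants else ""
    background = extract_background(plasma_variants, tracking)
    mean_obs, n_used = observed_mean_af(plasma_variants, tracking)
    seed_out = seed if isinstance(seed, int) else None
    if n_used == 0 or background.size < n_used:
        return classify_sample(sample_id, mean_obs, n_used, None,
                               iterations, alpha, seed_out)
    p = monte_carlo_pvalue(mean_obs, n_used, background, iterations, seed)
    return classify_sample(sample_id, mean_obs, n_used, p, iterations, alpha, seed_out)
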