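import numpy as np
import pytest

from ctdnatrack.germline import GermlineFeatureVector, GermlineModel, train_model
from ctdnatrack.io import AnnotationTables, VariantCall
from ctdnatrack.simulate import CohortSimConfig, simulate_cohort


def make_variant(
    chrom="chr17",
    pos=7577120,
    ref="A",
    alt="C",
    af=0.2,
    depth=1000,
    sample_type="tissue",
    subject_id="S001",
    sample_id="S001-T0",
    **kwargs,
):
    """Variant builder with consistent counts derived from af and depth."""
    alt_count = int(round(af * depth))
    return VariantCall(
        subject_id=subject_id, sample_id=sample_id, sample_type=sample_type,
        chrom=chrom, pos=pos, ref=ref, alt=alt, depth=depth,
        alt_count=alt_count, af=alt_count / depth, **kwargs)


def make_feature(
    max_pop_af=0.0, n_dbs_present=0, somatic_evidence_count=0,
    observed_af=0.1, is_hotspot=False,
):
    return GermlineFeatureVector(
        max_pop_af=max_pop_af, n_dbs_present=n_dbs_present,
        somatic_evidence_count=somatic_evidence_count, observed_af=observed_af,
        af_distance_to_het=abs(observed_af - 0.5),
        af_distance_to_hom=abs(observed_af - 1.0),
        is_hotspot=is_hotspot)


def make_training_set(rng, n_per_class=150):
    """Separable-but-realistic labeled features: germline near AF 0.5/1.0 with
    database presence, somatic at low-to-moderate AF and mostly absent from
    population databases."""
    labeled = []
    for _ in range(n_per_class):
        hom = rng.random() < 0.3
        target = 1.0 if hom else 0.5
        af = float(np.clip(rng.normal(target, 0.03), 0.0, 1.0))
        labeled.append((make_feature(
            max_pop_af=float(rng.uniform(0.05, 0.5)),
            n_dbs_present=int(rng.integers(1, 4)),
            observed_af=af), "germline"))
    for _ in range(n_per_class):
        af = float(rng.uniform(0.005, 0.45))
        pop = float(rng.uniform(0.0, 0.05)) if rng.random() < 0.2 else 0.0
        labeled.append((make_feature(
            max_pop_af=pop,
            n_dbs_present=int(pop > 0),
            somatic_evidence_count=int(rng.poisson(3)),
            observed_af=af), "somatic"))
    return labeled


@pytest.fixture(scope="session")
def trained_model():
    rng = np.random.default_rng(20240915)
    return train_model(make_training_set(rng), seed=0)


@pytest.fixture(scope="session")
def rule_model():
    """Hand-built score whose germline prediction depends only on
    max_pop_af >= 0.1; used where criteria must toggle independently."""
    weights = {name: 0.0 for name in (
        "max_pop_af", "n_dbs_present", "somatic_evidence_count",
        "observed_af", "af_distance_to_het", "af_distance_to_hom")}
    weights["max_pop_af"] = 100.0
    return GermlineModel(weights=weights, intercept=-10.0, threshold=0.5)


@pytest.fixture()
def annotations():
    """Small hand-built annotation bundle.

    Mask covers chr17 positions 101..200 (BED chr17 100 200); hotspot at
    chr7:55086725 G>T; population and evidence entries as listed.
    """
    from intervaltree import IntervalTree

    ann = AnnotationTables()
    ann.pop_af_by_db = {
        "exac": {("chr1", 1000, "A", "G"): 0.30, ("chr2", 2000, "C", "T"): 0.02},
        "dbsnp": {("chr1", 1000, "A", "G"): 0.28, ("chr3", 3000, "G", "A"): 0.35},
        "g1000": {("chr1", 1000, "A", "G"): 0.25},
    }
    ann.somatic_evidence = {("chr7", 55086725, "G", "T"): 120}
    tree = IntervalTree()
    tree.addi(101, 201)
    ann.region_mask = {"chr17": tree}
    ann.hotspot_list = {("chr7", 55086725, "G", "T")}
    return ann


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject default-condition cohort shared across tests."""
    return simulate_cohort(CohortSimConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (71-subject) default cohort; session-scoped because the
    recovery checks reuse it."""
    return simulate_cohort(CohortSimConfig(n_subjects=71, seed=5))
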