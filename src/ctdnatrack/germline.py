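"""Germline vs somatic classification without a matched normal.

Tumor-only calling cannot see the patient's constitutional genome, so
germline polymorphisms must be separated from somatic mutations using
population databases and the observed allele frequency: germline variants
tend to sit near 0.5 (heterozygous) or 1.0 (homozygous) and to be catalogued
in population databases, while somatic mutations are usually absent from
them and can occur at any allele fraction. A logistic score over these
feature families drives the decision; hotspot (whitelist) variants are never
called germline on allele-frequency evidence alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io import AnnotationTables, VariantCall

__all__ = [
    "GermlineFeatureVector",
    "GermlineModel",
    "featurize",
    "train_model",
    "classify",
    "save_model",
    "load_model",
]

# Fixed feature order; the hotspot flag is a hard override, not a feature.
FEATURE_NAMES = (
    "max_pop_af",
    "n_dbs_present",
    "somatic_evidence_count",
    "observed_af",
    "af_distance_to_het",
    "af_distance_to_hom",
)

GERMLINE, SOMATIC = "germline", "somatic"


@dataclass(slots=True)
class GermlineFeatureVector:
    """Database- and allele-frequency-derived features for one variant."""

    max_pop_af: float
    n_dbs_present: int
    somatic_evidence_count: int
    observed_af: float
    af_distance_to_het: float
    af_distance_to_hom: float
    is_hotspot: bool = False

    def __post_init__(self) -> None:
        for name in ("max_pop_af", "observed_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([
            self.max_pop_af,
            float(self.n_dbs_present),
            float(self.somatic_evidence_count),
            self.observed_af,
            self.af_distance_to_het,
            self.af_distance_to_hom,
        ])


@dataclass
class GermlineModel:
    """Logistic score over the germline feature families.

    ``weights`` point in the germline direction: a higher score means more
    germline-like. The coefficient on ``max_pop_af`` is constrained
    non-negative (and the one on ``somatic_evidence_count`` non-positive) so
    that raising a variant's population frequency can never flip it from
    germline to somatic.
    """

    weights: dict[str, float]
    intercept: float
    threshold: float = 0.5
    seed: int = 0
    n_train: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        missing = set(FEATURE_NAMES) - set(self.weights)
        if missing:
            raise ValueError(f"model missing weights for {sorted(missing)}")

    def _weight_vector(self) -> np.ndarray:
        return np.array([self.weights[n] for n in FEATURE_NAMES])

    def germline_probability(self, fv: GermlineFeatureVector) -> float:
        z = float(self._weight_vector() @ fv.to_array()) + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict_is_germline(self, fv: GermlineFeatureVector) -> bool:
        if fv.is_hotspot:  # whitelist override precedes scoring
            return False
        return self.germline_probability(fv) >= self.threshold


def featurize(variant: VariantCall, annotations: AnnotationTables) -> GermlineFeatureVector:
    """Build the classifier features for one variant.

    Absent database entries yield zero frequencies/counts, never missing
    values, so downstream arithmetic is total.
    """
    key = variant.key
    af = variant.af
    return GermlineFeatureVector(
        max_pop_af=annotations.max_pop_af(key),
        n_dbs_present=annotations.n_dbs_present(key),
        somatic_evidence_count=annotations.evidence_count(key),
        observed_af=af,
        af_distance_to_het=abs(af - 0.5),
        af_distance_to_hom=abs(af - 1.0),
        is_hotspot=variant.is_hotspot or annotations.is_hotspot(key),
    )


def train_model(
    labeled_features: Sequence[tuple[GermlineFeatureVector, str]],
    seed: int = 0,
    threshold: float = 0.5,
    C: float = 10.0,
) -> GermlineModel:
    """Fit the logistic germline score on labeled feature vectors.

    Labels are ``"germline"`` / ``"somatic"``. Training is deterministic
    given the data (lbfgs on a convex objective); ``seed`` is recorded as
    training metadata.
    """
    labels = {label for _, label in labeled_features}
    if labels != {GERMLINE, SOMATIC}:
        raise ValueError(
            f"training data must contain both classes, got {sorted(labels)}")
    X = np.vstack([fv.to_array() for fv, _ in labeled_features])
    y = np.array([1 if label == GERMLINE else 0 for _, label in labeled_features])
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X, y)
    coef = clf.coef_[0].copy()
    idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    # Enforce monotonicity: population evidence only ever pushes toward
    # germline, somatic catalog evidence only toward somatic.
    coef[idx["max_pop_af"]] = max(coef[idx["max_pop_af"]], 0.0)
    coef[idx["n_dbs_present"]] = max(coef[idx["n_dbs_present"]], 0.0)
    coef[idx["somatic_evidence_count"]] = min(coef[idx["somatic_evidence_count"]], 0.0)
    return GermlineModel(
        weights={n: float(coef[idx[n]]) for n in FEATURE_NAMES},
        intercept=float(clf.intercept_[0]),
        threshold=threshold,
        seed=seed,
        n_train=len(labeled_features),
    )


def classify(
    variants: Iterable[VariantCall],
    model: GermlineModel,
    annotations: AnnotationTables,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition variants into (predicted_germline, putative_somatic).

    The partition is exhaustive and exclusive; whitelist variants are
    always routed to the somatic side regardless of allele frequency.
    """
    predicted_germline: list[VariantCall] = []
    putative_somatic: list[VariantCall] = []
    for v in variants:
        fv = featurize(v, annotations)
        if model.predict_is_germline(fv):
            predicted_germline.append(v)
        else:
            putative_somatic.append(v)
    return predicted_germline, putative_somatic


def save_model(model: GermlineModel, path: str | Path) -> None:
    """Serialize the model to a flat text file (feature, weight) that
    reloads bit-equal (float repr round-trips in Python)."""
    with open(Path(path), "w") as fh:
        fh.write("# ctdnatrack germline model v1\n")
        for name in FEATURE_NAMES:
            fh.write(f"{name}\t{model.weights[name]!r}\n")
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write(f"threshold\t{model.threshold!r}\n")
        fh.write(f"seed\t{model.seed}\n")
        fh.write(f"n_train\t{model.n_train}\n")


def load_model(path: str | Path) -> GermlineModel:
    weights: dict[str, float] = {}
    intercept = 0.0
    threshold = 0.5
    seed = 0
    n_train = 0
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")
            if name == "intercept":
                intercept = float(value)
            elif name == "threshold":
                threshold = float(value)
            elif name == "seed":
                seed = int(value)
            elif name == "n_train":
                n_train = int(value)
            else:
                weights[name] = float(value)
    return GermlineModel(weights=weights, intercept=intercept,
                         threshold=threshold, seed=seed, n_train=n_train)
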