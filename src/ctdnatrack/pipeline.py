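"""End-to-end pipeline: cohort in, KM/log-rank/Cox summaries out.

Stages: (synthesize or load a cohort) -> train/load the germline model ->
FFPE post-call filters and tracking sets -> per-sample Monte Carlo ctDNA
detection -> longitudinal monitoring (total ctDNA, molecular progression,
lead time) -> PFS survival analysis stratified by ctDNA status.

Reruns with the same config are byte-identical: every source of randomness
is derived from the master seed through a documented SeedSequence scheme
(stage index, then sample index), and no output embeds a timestamp.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect as det
from . import germline as gl
from . import io as vio
from . import monitor as mon
from . import survival as surv
from .filters import FFPEFilterParams, TrackingSet, apply_ffpe_filters, build_tracking_set
from .simulate import CohortSimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort_dir", "build_timelines"]

logger = logging.getLogger("ctdnatrack")

# Stage indices of the seed-derivation scheme (master SeedSequence children).
_STAGE_SIM, _STAGE_GERMLINE, _STAGE_DETECT = 0, 1, 2

POP_DBS = ("exac", "dbsnp", "g1000")
SOMATIC_DBS = ("cosmic", "tcga")


@dataclass
class PipelineConfig:
    """Single-config orchestration of every stage."""

    out_dir: str = "results"
    input_dir: str | None = None       # existing cohort bundle; or synthesize
    synthesize: bool = True
    sim: CohortSimConfig = field(default_factory=CohortSimConfig)
    germline_model_path: str | None = None  # pre-trained model; else train
    af_min: float = 0.05
    af_min_hotspot: float = 0.03
    exac_max: float = 0.01
    include_synonymous: bool = True
    iterations: int = 10_000
    alpha: float = 0.01
    k_increases: int = 2
    progression_rule: str = "any_variant"
    haploid_genome_mass_ng: float = mon.HAPLOID_GENOME_MASS_NG
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("af_min", "af_min_hotspot", "exac_max", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def stage_seed(self, stage: int) -> int:
        child = np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]
        return int(child.generate_state(1)[0] % 2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            sim_raw = dict(raw["sim"])
            from .simulate import BackgroundErrorShape, TrajectoryModel
            if "background_error_shape" in sim_raw:
                sim_raw["background_error_shape"] = BackgroundErrorShape(
                    **sim_raw["background_error_shape"])
            if "tumor_fraction_trajectory" in sim_raw:
                tm = dict(sim_raw["tumor_fraction_trajectory"])
                if "resistance_onset_range" in tm:
                    tm["resistance_onset_range"] = tuple(tm["resistance_onset_range"])
                sim_raw["tumor_fraction_trajectory"] = TrajectoryModel(**tm)
            for name in ("samples_per_subject_range", "n_true_somatic_range",
                         "tissue_af_range"):
                if name in sim_raw:
                    sim_raw[name] = tuple(sim_raw[name])
            raw["sim"] = CohortSimConfig(**sim_raw)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class LoadedCohort:
    tissue_by_subject: dict[str, list[vio.VariantCall]]
    plasma_by_sample: dict[str, list[vio.VariantCall]]
    manifest: list[vio.SampleRecord]
    clinical: dict[str, vio.ClinicalRecord]
    recist: dict[str, list[tuple[int, str]]]
    annotations: vio.AnnotationTables
    truth_labels: dict[tuple[str, vio.VariantKey], str]  # (subject, key) -> label


def load_cohort_dir(path: str | Path) -> LoadedCohort:
    """Read a cohort bundle directory back through the I/O layer."""
    path = Path(path)
    for required in ("variants_tissue.tsv", "variants_plasma.tsv", "manifest.tsv",
                     "clinical.tsv", "recist.tsv", "mask.bed", "hotspots.tsv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"cohort bundle incomplete: missing {path / required}")
    tissue = vio.read_variant_table(path / "variants_tissue.tsv")
    plasma = vio.read_variant_table(path / "variants_plasma.tsv")
    tissue_by_subject: dict[str, list[vio.VariantCall]] = {}
    for v in tissue:
        tissue_by_subject.setdefault(v.subject_id, []).append(v)
    plasma_by_sample: dict[str, list[vio.VariantCall]] = {}
    for v in plasma:
        plasma_by_sample.setdefault(v.sample_id, []).append(v)
    annotations = vio.load_annotations(
        pop_tables={db: path / f"pop_{db}.tsv" for db in POP_DBS
                    if (path / f"pop_{db}.tsv").exists()},
        somatic_tables={db: path / f"somatic_{db}.tsv" for db in SOMATIC_DBS
                        if (path / f"somatic_{db}.tsv").exists()},
        mask_bed=path / "mask.bed",
        hotspot_path=path / "hotspots.tsv",
    )
    truth_labels: dict[tuple[str, vio.VariantKey], str] = {}
    gt_path = path / "ground_truth_variants.tsv"
    if gt_path.exists():
        with open(gt_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                key = vio.normalize_key(row["chrom"], int(row["pos"]),
                                        row["ref"], row["alt"])
                truth_labels[(row["subject_id"], key)] = row["label"]
    return LoadedCohort(
        tissue_by_subject=tissue_by_subject,
        plasma_by_sample=plasma_by_sample,
        manifest=vio.read_manifest(path / "manifest.tsv"),
        clinical={c.subject_id: c for c in vio.read_clinical(path / "clinical.tsv")},
        recist=vio.read_recist(path / "recist.tsv"),
        annotations=annotations,
        truth_labels=truth_labels,
    )


def _train_germline_from_truth(cohort: LoadedCohort, seed: int) -> gl.GermlineModel:
    """Train the germline classifier on the bundle's labeled variants
    (germline vs somatic; background alterations are excluded)."""
    labeled: list[tuple[gl.GermlineFeatureVector, str]] = []
    for subject_id, variants in cohort.tissue_by_subject.items():
        for v in variants:
            label = cohort.truth_labels.get((subject_id, v.key))
            if label in (gl.GERMLINE, gl.SOMATIC):
                labeled.append((gl.featurize(v, cohort.annotations), label))
    for sample_variants in cohort.plasma_by_sample.values():
        for v in sample_variants:
            label = cohort.truth_labels.get((v.subject_id, v.key))
            if label in (gl.GERMLINE, gl.SOMATIC):
                labeled.append((gl.featurize(v, cohort.annotations), label))
    return gl.train_model(labeled, seed=seed)


def build_timelines(
    cohort: LoadedCohort,
    detections: dict[str, det.DetectionResult],
    haploid_genome_mass_ng: float = mon.HAPLOID_GENOME_MASS_NG,
    tracking: dict[str, TrackingSet] | None = None,
) -> dict[str, mon.SubjectTimeline]:
    """Assemble per-subject timelines from manifest, plasma AFs, detection
    results and clinical anchors. Per-sample AF maps are restricted to the
    subject's tracking set when one is supplied."""
    timelines: dict[str, mon.SubjectTimeline] = {}
    by_subject: dict[str, list[vio.SampleRecord]] = {}
    for rec in cohort.manifest:
        if rec.sample_type == "plasma":
            by_subject.setdefault(rec.subject_id, []).append(rec)
    for subject_id, records in by_subject.items():
        records.sort(key=lambda r: r.collection_day)
        samples = []
        tset = tracking.get(subject_id) if tracking else None
        for rec in records:
            variants = cohort.plasma_by_sample.get(rec.sample_id, [])
            af_map = {v.key: v.af for v in variants
                      if tset is None or v.key in tset.variant_keys}
            detection = detections.get(rec.sample_id)
            level = mon.total_ctdna_level(af_map, rec.input_mass_ng,
                                          haploid_genome_mass_ng)
            samples.append(mon.TimelineSample(
                record=rec, af_by_variant=af_map, detection=detection,
                total_ctdna=level))
        clin = cohort.clinical.get(subject_id)
        timelines[subject_id] = mon.SubjectTimeline(
            subject_id=subject_id,
            samples=samples,
            recist_events=cohort.recist.get(subject_id, []),
            death_day=clin.death_day if clin else None,
            last_imaging_day=clin.last_imaging_day if clin else None,
            treatment_start_day=clin.treatment_start_day if clin else None,
        )
    return timelines


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the results directory.

    Writes tracking_sets.tsv, detections.tsv, monitoring.tsv,
    survival_records.tsv, survival_summary.tsv and a manifest.json of seeds
    and output checksums.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: cohort
    if config.synthesize:
        cohort_dir = out / "cohort"
        sim_config = CohortSimConfig(**{**asdict(config.sim),
                                        "seed": config.stage_seed(_STAGE_SIM)})
        from .simulate import BackgroundErrorShape, TrajectoryModel
        sim_config.background_error_shape = BackgroundErrorShape(
            **asdict(config.sim.background_error_shape))
        sim_config.tumor_fraction_trajectory = TrajectoryModel(
            **asdict(config.sim.tumor_fraction_trajectory))
        simulate_cohort(sim_config, out_dir=cohort_dir, overwrite=True)
        logger.info("simulate: wrote cohort to %s (%.1fs)", cohort_dir,
                    time.monotonic() - t0)
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when synthesize is false")
        cohort_dir = Path(config.input_dir)
    cohort = load_cohort_dir(cohort_dir)

    # stage: germline model
    if config.germline_model_path:
        model = gl.load_model(config.germline_model_path)
    else:
        if not cohort.truth_labels:
            raise ValueError("no germline model path and no ground-truth labels "
                             "to train on")
        model = _train_germline_from_truth(cohort, seed=config.stage_seed(_STAGE_GERMLINE))
    gl.save_model(model, out / "germline_model.txt")
    logger.info("germline: model trained on %d variants (%.1fs)", model.n_train,
                time.monotonic() - t0)

    # stage: FFPE filters -> tracking sets
    params = FFPEFilterParams(af_min=config.af_min,
                              af_min_hotspot=config.af_min_hotspot,
                              exac_max=config.exac_max)
    tracking: dict[str, TrackingSet] = {}
    with open(out / "filter_outcomes.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "chrom", "pos", "ref", "alt", "af",
                         "passed", "failed_criteria"])
        for subject_id in sorted(cohort.tissue_by_subject):
            outcomes = apply_ffpe_filters(cohort.tissue_by_subject[subject_id],
                                          cohort.annotations, model, params)
            tracking[subject_id] = build_tracking_set(
                outcomes, subject_id, include_synonymous=config.include_synonymous)
            for o in outcomes:
                writer.writerow([subject_id, o.variant.chrom, o.variant.pos,
                                 o.variant.ref, o.variant.alt, f"{o.variant.af:.6f}",
                                 str(o.passed).lower(),
                                 ",".join(sorted(o.failed_criteria))])
    with open(out / "tracking_sets.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "chrom", "pos", "ref", "alt"])
        for subject_id in sorted(tracking):
            for key in sorted(tracking[subject_id].variant_keys):
                writer.writerow([subject_id, *key])
    logger.info("filters: %d tracking sets (%.1fs)", len(tracking),
                time.monotonic() - t0)

    # stage: per-sample detection (seed derived per sample index)
    detect_ss = np.random.SeedSequence(
        [config.stage_seed(_STAGE_DETECT)])
    sample_ids = sorted(cohort.plasma_by_sample)
    sample_seeds = {sid: int(child.generate_state(1)[0] % 2**31)
                    for sid, child in zip(sample_ids, detect_ss.spawn(len(sample_ids)))}
    detections: dict[str, det.DetectionResult] = {}
    for sid in sample_ids:
        variants = cohort.plasma_by_sample[sid]
        subject_id = variants[0].subject_id
        tset = tracking.get(subject_id)
        if tset is None:
            continue
        # Plasma somatic calls are derived by filtering out predicted
        # germline variants before the presence test, so constitutional
        # heterozygous sites (AF ~ 0.5) never enter the background null.
        _, putative_somatic = gl.classify(variants, model, cohort.annotations)
        detections[sid] = det.detect_sample(
            putative_somatic, tset, iterations=config.iterations,
            alpha=config.alpha, seed=sample_seeds[sid])
    with open(out / "detections.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "observed_mean_af", "empirical_p",
                         "iterations", "n_used", "call", "seed"])
        for sid in sample_ids:
            if sid not in detections:
                continue
            r = detections[sid]
            p = "" if r.empirical_p is None else f"{r.empirical_p:.6g}"
            writer.writerow([r.sample_id, f"{r.observed_mean_af:.8f}", p,
                             r.iterations, r.n_used, r.call, r.seed])
    logger.info("detect: %d samples (%.1fs)", len(detections), time.monotonic() - t0)

    # stage: monitoring
    timelines = build_timelines(cohort, detections, config.haploid_genome_mass_ng,
                                tracking)
    with open(out / "monitoring.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "mp_called", "mp_call_day", "first_pd_day",
                         "lead_time_days"])
        for subject_id in sorted(timelines):
            tl = timelines[subject_id]
            if len(tl.samples) < 2:
                continue
            mp = mon.detect_molecular_progression(
                tl, k_increases=config.k_increases, rule=config.progression_rule)
            lead = mon.lead_time(mp, tl)
            writer.writerow([
                subject_id, str(mp.called).lower(),
                "" if mp.call_day is None else mp.call_day,
                "" if tl.first_pd_day() is None else tl.first_pd_day(),
                "" if lead is None else lead])
    with open(out / "ctdna_levels.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "sample_id", "collection_day", "total_ctdna_mge"])
        for subject_id in sorted(timelines):
            for s in timelines[subject_id].samples:
                writer.writerow([subject_id, s.record.sample_id, s.day,
                                 f"{s.total_ctdna:.4f}"])
    logger.info("monitor: %d timelines (%.1fs)", len(timelines), time.monotonic() - t0)

    # stage: survival
    summary_rows = []
    records_by_strat: dict[str, list[surv.SurvivalRecord]] = {}
    for which in ("first", "last"):
        records = []
        for subject_id in sorted(timelines):
            tl = timelines[subject_id]
            try:
                rec = surv.compute_pfs(tl)
            except ValueError:
                continue
            rec.group = surv.ctdna_group(tl, which=which)
            if rec.group is not None:
                records.append(rec)
        records_by_strat[which] = records
        pos = [r for r in records if r.group == surv.CTDNA_POSITIVE]
        neg = [r for r in records if r.group == surv.CTDNA_NEGATIVE]
        if not pos or not neg:
            logger.warning("survival(%s): a stratum is empty; skipping tests", which)
            continue
        km_pos, km_neg = surv.km_estimate(pos), surv.km_estimate(neg)
        chi2, p_lr = surv.logrank_test(pos, neg)
        cox = surv.cox_univariate(records, covariate="group")
        hr, lo, hi, p_wald = (cox.hazard_ratios.get(surv.CTDNA_POSITIVE,
                                                    (float("nan"),) * 4))
        summary_rows.append({
            "stratification": which,
            "n_positive": len(pos), "n_negative": len(neg),
            "median_pfs_positive": km_pos.median, "median_pfs_negative": km_neg.median,
            "logrank_chi2": chi2, "logrank_p": p_lr,
            "cox_hr": hr, "cox_ci_low": lo, "cox_ci_high": hi,
            "cox_p": p_wald, "cox_converged": cox.converged,
        })
    with open(out / "survival_records.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stratification", "subject_id", "time_days", "event", "group"])
        for which, records in records_by_strat.items():
            for r in records:
                writer.writerow([which, r.subject_id, r.time_days,
                                 str(r.event).lower(), r.group])
    with open(out / "survival_summary.tsv", "w", newline="") as fh:
        if summary_rows:
            writer = csv.DictWriter(fh, fieldnames=list(summary_rows[0]),
                                    delimiter="\t", lineterminator="\n")
            writer.writeheader()
            for row in summary_rows:
                writer.writerow(row)
    logger.info("survival: %d strata summaries (%.1fs)", len(summary_rows),
                time.monotonic() - t0)

    # manifest of seeds and checksums (no timestamps: reruns are byte-identical)
    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "ctdnatrack",
        "seed": config.seed,
        "stage_seeds": {"simulate": config.stage_seed(_STAGE_SIM),
                        "germline": config.stage_seed(_STAGE_GERMLINE),
                        "detect": config.stage_seed(_STAGE_DETECT)},
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete in %.1fs -> %s", time.monotonic() - t0, out)
    return out
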