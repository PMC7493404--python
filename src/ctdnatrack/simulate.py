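"""Ground-truth-labeled synthetic cohorts for the monitoring pipeline.

The generator emulates a tumor-informed liquid-biopsy study: each subject
contributes a baseline FFPE tissue sample and a series of plasma draws on a
fixed gene panel. Somatic variants carry a per-variant clonal fraction; a
plasma variant's expected allele frequency is clonal fraction x tumor
fraction at the draw day, sampled binomially in the de-duplicated depth.
Background sequencing error is beta-binomial (overdispersed relative to pure
binomial, as empirical NGS background is), germline polymorphisms sit near
AF 0.5/1.0 and are catalogued in the emitted population tables, and
progression-free survival follows an exponential model whose hazard is
multiplied by a configured ratio when the subject's first post-treatment
draw carries detectable tumor DNA.

Every emitted variant carries a ground-truth label (somatic / germline /
background), every sample a true tumor fraction, and every subject a true
arm, molecular-progression day and PFS outcome, so recovery of each pipeline
stage can be measured directly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    AnnotationTables,
    ClinicalRecord,
    SampleRecord,
    VariantCall,
    VariantKey,
    write_clinical,
    write_manifest,
    write_recist,
    write_variant_table,
)

__all__ = [
    "CohortSimConfig",
    "BackgroundErrorShape",
    "TrajectoryModel",
    "Panel",
    "SubjectTruth",
    "SubjectSim",
    "CohortBundle",
    "build_panel",
    "simulate_background",
    "simulate_subject",
    "simulate_cohort",
    "simulate_survival_records",
    "write_cohort",
]

# A compact stand-in for a hybrid-capture lung-cancer panel: recurrently
# mutated genes with hg19-style anchor coordinates.
PANEL_GENES = [
    ("TP53", "chr17", 7571720), ("KRAS", "chr12", 25358180),
    ("KEAP1", "chr19", 10486125), ("EGFR", "chr7", 55086725),
    ("BRAF", "chr7", 140419127), ("STK11", "chr19", 1205798),
    ("ERBB2", "chr17", 37844393), ("MET", "chr7", 116312459),
    ("NPAP1", "chr15", 24920598), ("CSMD3", "chr8", 113235157),
    ("LRRTM4", "chr2", 76974845), ("ALK", "chr2", 29415640),
    ("PIK3CA", "chr3", 178866311), ("PTEN", "chr10", 89623195),
    ("NF1", "chr17", 29421945), ("RB1", "chr13", 48877883),
    ("CDKN2A", "chr9", 21967751), ("SMAD4", "chr18", 48556583),
    ("ATM", "chr11", 108093559), ("FGFR1", "chr8", 38268656),
]

_BASES = "ACGT"


@dataclass(slots=True)
class BackgroundErrorShape:
    """Per-position error-AF distribution: error rate ~ Beta with the given
    mean and concentration (a = mean*conc, b = (1-mean)*conc); alt counts are
    then Binomial(depth, rate), i.e. beta-binomial marginally."""

    mean_error: float = 1e-4
    concentration: float = 20_000.0

    def beta_params(self) -> tuple[float, float]:
        a = self.mean_error * self.concentration
        b = (1.0 - self.mean_error) * self.concentration
        return a, b


@dataclass(slots=True)
class TrajectoryModel:
    """Piecewise-exponential tumor-fraction trajectories per arm.

    Responders decline multiplicatively on therapy; progressors decline
    until a resistance-onset day, then grow monotonically (the subject's
    true molecular-progression day).
    """

    decline_per_day: float = 0.03
    growth_per_day: float = 0.025
    resistance_onset_range: tuple[float, float] = (30.0, 150.0)
    progressor_fraction: float = 0.6
    tf0_log_mean: float = math.log(0.01)
    tf0_log_sd: float = 1.5
    tf_cap: float = 0.35


@dataclass
class CohortSimConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults encode the cohort shape the analysis assumes: 71 subjects with
    2-18 plasma draws each (about 6 on average, one per 21-day cycle),
    mean de-duplicated depth 2779 (plasma) and 1116 (tissue), an average of
    six true somatic variants per subject with tissue AFs spanning roughly
    3.3-86.8%, and a true hazard ratio of 2.3 for ctDNA-bearing status at
    the first post-treatment draw.
    """

    n_subjects: int = 71
    samples_per_subject_range: tuple[int, int] = (2, 18)
    samples_per_subject_mean: float = 6.0
    sample_interval_days: int = 21
    panel_positions: int = 2000
    background_error_shape: BackgroundErrorShape = field(default_factory=BackgroundErrorShape)
    depth_plasma_mean: float = 2779.0
    depth_tissue_mean: float = 1116.0
    depth_cv: float = 0.1
    n_true_somatic_range: tuple[int, int] = (1, 15)
    n_somatic_mean: float = 6.0
    tissue_af_range: tuple[float, float] = (0.034, 0.86)
    germline_rate: float = 8.0
    hotspot_fraction: float = 0.15
    synonymous_fraction: float = 0.15
    artifact_rate: float = 0.7
    tumor_fraction_trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)
    tf_positive_threshold: float = 0.003
    hazard_ratio_true: float = 2.3
    baseline_median_pfs_days: float = 270.0
    death_fraction: float = 0.1
    imaging_interval_days: int = 63
    censoring_rate: float = 0.35
    masked_fraction: float = 0.02
    treatment_start_day: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("samples_per_subject_range", "n_true_somatic_range", "tissue_af_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        for name in ("censoring_rate", "hotspot_fraction", "synonymous_fraction",
                     "masked_fraction", "death_fraction", "tf_positive_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hazard_ratio_true <= 0:
            raise ValueError("hazard_ratio_true must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "background_error_shape" in raw:
            raw["background_error_shape"] = BackgroundErrorShape(**raw["background_error_shape"])
        if "tumor_fraction_trajectory" in raw:
            tm = dict(raw["tumor_fraction_trajectory"])
            if "resistance_onset_range" in tm:
                tm["resistance_onset_range"] = tuple(tm["resistance_onset_range"])
            raw["tumor_fraction_trajectory"] = TrajectoryModel(**tm)
        for name in ("samples_per_subject_range", "n_true_somatic_range", "tissue_af_range"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)


@dataclass
class Panel:
    """Assayed positions with fixed ref/alt alleles, plus cohort-level
    polymorphic sites, hotspot sites and the repetitive-region mask."""

    genes: list[str]
    chroms: list[str]
    positions: list[int]
    refs: list[str]
    alts: list[str]
    polymorphic_idx: list[int]
    pop_afs: dict[str, dict[int, float]]  # db -> panel index -> population af
    hotspot_idx: list[int]
    evidence: dict[str, dict[int, int]]   # db -> panel index -> count
    masked_idx: set[int]
    mask_intervals: list[tuple[str, int, int]]  # BED: chrom, 0-based start, end

    def key(self, i: int) -> VariantKey:
        return (self.chroms[i], self.positions[i], self.refs[i], self.alts[i])

    @property
    def size(self) -> int:
        return len(self.positions)

    def somatic_eligible(self) -> list[int]:
        blocked = set(self.polymorphic_idx) | self.masked_idx
        return [i for i in range(self.size) if i not in blocked]

    def annotations(self) -> AnnotationTables:
        from intervaltree import IntervalTree

        ann = AnnotationTables()
        for db, table in self.pop_afs.items():
            ann.pop_af_by_db[db] = {self.key(i): af for i, af in table.items()}
        for table in self.evidence.values():
            for i, count in table.items():
                key = self.key(i)
                ann.somatic_evidence[key] = ann.somatic_evidence.get(key, 0) + count
        for chrom, start, end in self.mask_intervals:
            ann.region_mask.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
        for tree in ann.region_mask.values():
            tree.merge_overlaps(strict=False)
        ann.hotspot_list = {self.key(i) for i in self.hotspot_idx}
        return ann


@dataclass(slots=True)
class SubjectTruth:
    """Ground-truth labels for one subject's simulated data."""

    subject_id: str
    arm: str  # "responder" | "progressor"
    variant_labels: dict[VariantKey, str]  # somatic | germline | background
    tf_by_sample: dict[str, float]
    molecular_progression_day: int | None
    pfs_time_days: int
    pfs_event: bool
    ctdna_bearing: bool
    hazard_ratio_true: float


@dataclass
class SubjectSim:
    subject_id: str
    tissue_variants: list[VariantCall]
    plasma_tables: list[list[VariantCall]]
    sample_records: list[SampleRecord]
    clinical: ClinicalRecord
    recist_events: list[tuple[int, str]]
    truth: SubjectTruth


@dataclass
class CohortBundle:
    config: CohortSimConfig
    panel: Panel
    subjects: list[SubjectSim]
    annotations: AnnotationTables


def _ref_alt_for(pos: int) -> tuple[str, str]:
    r = (pos * 2654435761) % 4
    a = (r + 1 + pos % 3) % 4
    return _BASES[r], _BASES[a]


def build_panel(config: CohortSimConfig) -> Panel:
    """Deterministic panel layout (positions, alleles, databases, mask) for a
    given config; shared by every subject of a cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9A4E1]))
    per_gene = math.ceil(config.panel_positions / len(PANEL_GENES))
    genes, chroms, positions, refs, alts = [], [], [], [], []
    for gene, chrom, start in PANEL_GENES:
        for i in range(per_gene):
            if len(positions) >= config.panel_positions:
                break
            pos = start + 3 * i
            ref, alt = _ref_alt_for(pos)
            genes.append(gene)
            chroms.append(chrom)
            positions.append(pos)
            refs.append(ref)
            alts.append(alt)
    size = len(positions)

    # Repetitive-region mask: contiguous blocks covering ~masked_fraction.
    masked_idx: set[int] = set()
    mask_intervals: list[tuple[str, int, int]] = []
    n_masked = int(config.masked_fraction * size)
    block = max(4, per_gene // 10)
    while len(masked_idx) < n_masked:
        start_i = int(rng.integers(0, size - block))
        gene0 = genes[start_i]
        run = [i for i in range(start_i, min(start_i + block, size)) if genes[i] == gene0]
        if not run:
            continue
        masked_idx.update(run)
        lo, hi = positions[run[0]], positions[run[-1]]
        mask_intervals.append((chroms[run[0]], lo - 1, hi))  # BED covers lo..hi 1-based

    # Polymorphic (germline-capable) sites with per-database population AFs.
    unmasked = [i for i in range(size) if i not in masked_idx]
    n_poly = max(50, size // 10)
    polymorphic_idx = sorted(rng.choice(unmasked, size=min(n_poly, len(unmasked)),
                                        replace=False).tolist())
    pop_afs: dict[str, dict[int, float]] = {"exac": {}, "dbsnp": {}, "g1000": {}}
    for i in polymorphic_idx:
        if rng.random() < 0.05:
            continue  # rare germline: absent from every database
        base_af = float(rng.uniform(0.01, 0.5))
        if rng.random() < 0.95:
            pop_afs["exac"][i] = base_af
        if rng.random() < 0.90:
            pop_afs["dbsnp"][i] = min(0.999, base_af * float(rng.uniform(0.8, 1.2)))
        if rng.random() < 0.70:
            pop_afs["g1000"][i] = min(0.999, base_af * float(rng.uniform(0.8, 1.2)))

    # Hotspot whitelist on somatic-eligible positions, with catalog evidence.
    eligible = [i for i in unmasked if i not in set(polymorphic_idx)]
    n_hot = min(30, len(eligible))
    hotspot_idx = sorted(rng.choice(eligible, size=n_hot, replace=False).tolist())
    evidence: dict[str, dict[int, int]] = {"cosmic": {}, "tcga": {}}
    for i in hotspot_idx:
        evidence["cosmic"][i] = 10 + int(rng.poisson(40))
        evidence["tcga"][i] = int(rng.poisson(10))
    for i in eligible:
        if i not in set(hotspot_idx) and rng.random() < 0.10:
            evidence["cosmic"][i] = 1 + int(rng.poisson(2))

    return Panel(genes=genes, chroms=chroms, positions=positions, refs=refs,
                 alts=alts, polymorphic_idx=polymorphic_idx, pop_afs=pop_afs,
                 hotspot_idx=hotspot_idx, evidence=evidence,
                 masked_idx=masked_idx, mask_intervals=sorted(mask_intervals))


def _depth(rng: np.random.Generator, mean: float, cv: float) -> int:
    return int(max(100, round(rng.normal(mean, cv * mean))))


def _make_call(panel: Panel, i: int, subject_id: str, sample_id: str,
               sample_type: str, depth: int, alt_count: int,
               hotspot_keys: set[VariantKey], synonymous: bool = False) -> VariantCall:
    chrom, pos, ref, alt = panel.key(i)
    key = (chrom, pos, ref, alt)
    return VariantCall(
        subject_id=subject_id, sample_id=sample_id, sample_type=sample_type,
        chrom=chrom, pos=pos, ref=ref, alt=alt, depth=depth,
        alt_count=alt_count, af=alt_count / depth if depth else 0.0,
        gene=panel.genes[i], cds_change=f"c.{pos % 2000 + 1}{ref}>{alt}",
        is_hotspot=key in hotspot_keys, is_synonymous=synonymous)


def simulate_background(
    config: CohortSimConfig,
    n_positions: int,
    depth: int,
    seed: int | np.random.Generator = 0,
    subject_id: str = "SIM",
    sample_id: str = "BG",
) -> list[VariantCall]:
    """Background allele alterations of one plasma sample.

    Per position an error rate is drawn from the configured beta shape and
    the alt count binomially at the given depth; positions with zero alt
    reads are omitted (they are not alterations).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = config.background_error_shape.beta_params()
    panel = build_panel(config)
    idx = np.arange(min(n_positions, panel.size))
    if a == 0:
        return []
    rates = rng.beta(a, b, size=idx.size)
    counts = rng.binomial(depth, rates)
    hot = {panel.key(i) for i in panel.hotspot_idx}
    out = []
    for i, k in zip(idx, counts):
        if k >= 1:
            out.append(_make_call(panel, int(i), subject_id, sample_id,
                                  "plasma", depth, int(k), hot))
    return out


def _tumor_fraction(tm: TrajectoryModel, arm: str, tf0: float,
                    resistance_day: float | None, day: float) -> float:
    tf = tf0 * math.exp(-tm.decline_per_day * day)
    if arm == "progressor" and resistance_day is not None and day >= resistance_day:
        tf_at_onset = tf0 * math.exp(-tm.decline_per_day * resistance_day)
        tf = tf_at_onset * math.exp(tm.growth_per_day * (day - resistance_day))
    return min(tf, tm.tf_cap)


@dataclass(slots=True)
class _ClinicalDraw:
    arm: str
    tf0: float
    resistance_day: float | None
    sample_days: list[int]
    bearing: bool
    pfs_time: int
    pfs_event: bool
    death: bool


def _simulate_subject_clinical(config: CohortSimConfig, rng: np.random.Generator) -> _ClinicalDraw:
    """Arm, tumor-fraction trajectory, draw schedule and survival outcome for
    one subject. Shared by the full generator and the survival-only fast path
    so both imply the same study conditions."""
    tm = config.tumor_fraction_trajectory
    lo, hi = config.samples_per_subject_range
    n_samples = int(np.clip(rng.poisson(config.samples_per_subject_mean), lo, hi))
    days = [0]
    for j in range(1, n_samples):
        jitter = int(rng.integers(-3, 4)) if j > 0 else 0
        day = max(days[-1] + 1, j * config.sample_interval_days + jitter)
        days.append(day)

    arm = "progressor" if rng.random() < tm.progressor_fraction else "responder"
    tf0 = min(float(rng.lognormal(tm.tf0_log_mean, tm.tf0_log_sd)), tm.tf_cap)
    resistance_day = (float(rng.uniform(*tm.resistance_onset_range))
                      if arm == "progressor" else None)

    post = [d for d in days if d > config.treatment_start_day]
    first_post_day = post[0] if post else days[-1]
    tf_first_post = _tumor_fraction(tm, arm, tf0, resistance_day, first_post_day)
    bearing = tf_first_post >= config.tf_positive_threshold

    lam0 = math.log(2.0) / config.baseline_median_pfs_days
    lam = lam0 * (config.hazard_ratio_true if bearing else 1.0)
    t_event = rng.exponential(1.0 / lam)
    r = config.censoring_rate
    lam_c = lam * r / (1.0 - r)
    t_cens = rng.exponential(1.0 / lam_c) if lam_c > 0 else math.inf
    event = t_event <= t_cens
    time = int(max(1, round(min(t_event, t_cens))))
    death = bool(event and rng.random() < config.death_fraction)
    return _ClinicalDraw(arm=arm, tf0=tf0, resistance_day=resistance_day,
                         sample_days=days, bearing=bearing, pfs_time=time,
                         pfs_event=event, death=death)


def simulate_subject(
    config: CohortSimConfig,
    seed: int | np.random.Generator,
    subject_id: str = "S001",
    panel: Panel | None = None,
) -> SubjectSim:
    """Simulate one subject: baseline tissue table, longitudinal plasma
    tables, manifest records, clinical timeline and ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel = panel or build_panel(config)
    tm = config.tumor_fraction_trajectory
    a_err, b_err = config.background_error_shape.beta_params()
    hotspot_keys = {panel.key(i) for i in panel.hotspot_idx}
    clin = _simulate_subject_clinical(config, rng)

    # --- true somatic variants (clonal fraction shared by tissue & plasma)
    lo_s, hi_s = config.n_true_somatic_range
    n_som = int(np.clip(rng.poisson(config.n_somatic_mean), max(lo_s, 1), hi_s))
    eligible = panel.somatic_eligible()
    non_hot = [i for i in eligible if i not in set(panel.hotspot_idx)]
    som_idx: list[int] = []
    for _ in range(n_som):
        pool = panel.hotspot_idx if rng.random() < config.hotspot_fraction else non_hot
        i = int(rng.choice(pool))
        if i not in som_idx:
            som_idx.append(i)
    clonal = {i: float(rng.beta(1.3, 4.5)) for i in som_idx}
    lo_af, hi_af = config.tissue_af_range
    tissue_af_true = {i: lo_af + clonal[i] * (hi_af - lo_af) for i in som_idx}
    synonymous = {i: bool(rng.random() < config.synonymous_fraction) for i in som_idx}

    # --- germline polymorphisms (constitutional; present in tissue & plasma)
    n_germ = int(rng.poisson(config.germline_rate))
    germ_idx = rng.choice(panel.polymorphic_idx,
                          size=min(n_germ, len(panel.polymorphic_idx)),
                          replace=False).astype(int).tolist()
    germ_af = {i: (0.5 if rng.random() < 2 / 3 else 1.0) for i in germ_idx}

    variant_labels: dict[VariantKey, str] = {}
    for i in som_idx:
        variant_labels[panel.key(i)] = "somatic"
    for i in germ_idx:
        variant_labels[panel.key(i)] = "germline"

    # --- baseline tissue table
    tissue_sample_id = f"{subject_id}-T0"
    tissue_depth = _depth(rng, config.depth_tissue_mean, config.depth_cv)
    tissue: list[VariantCall] = []
    for i in som_idx:
        alt = int(round(tissue_af_true[i] * tissue_depth))
        tissue.append(_make_call(panel, i, subject_id, tissue_sample_id, "tissue",
                                 tissue_depth, alt, hotspot_keys, synonymous[i]))
    for i in germ_idx:
        alt = int(rng.binomial(tissue_depth, min(germ_af[i], 0.999)))
        if alt >= 1:
            tissue.append(_make_call(panel, i, subject_id, tissue_sample_id,
                                     "tissue", tissue_depth, alt, hotspot_keys))
    # FFPE artifacts exercising the post-call filters: one masked-region call
    # and one low-AF call, labeled background in the ground truth.
    occupied = set(som_idx) | set(germ_idx)
    masked_pool = [i for i in panel.masked_idx if i not in occupied]
    if masked_pool and rng.random() < config.artifact_rate:
        i = int(rng.choice(masked_pool))
        alt = max(1, int(round(float(rng.uniform(0.05, 0.30)) * tissue_depth)))
        tissue.append(_make_call(panel, i, subject_id, tissue_sample_id,
                                 "tissue", tissue_depth, alt, hotspot_keys))
        variant_labels[panel.key(i)] = "background"
        occupied.add(i)
    low_pool = [i for i in non_hot if i not in occupied]
    if low_pool and rng.random() < config.artifact_rate:
        i = int(rng.choice(low_pool))
        alt = max(1, int(round(float(rng.uniform(0.031, 0.05)) * tissue_depth)))
        tissue.append(_make_call(panel, i, subject_id, tissue_sample_id,
                                 "tissue", tissue_depth, alt, hotspot_keys))
        variant_labels[panel.key(i)] = "background"
        occupied.add(i)

    # --- longitudinal plasma tables
    plasma_tables: list[list[VariantCall]] = []
    sample_records: list[SampleRecord] = [SampleRecord(
        subject_id=subject_id, sample_id=tissue_sample_id, sample_type="tissue",
        collection_day=0,
        input_mass_ng=float(np.clip(rng.lognormal(math.log(50), 0.6), 9, 200)),
    )]
    tf_by_sample: dict[str, float] = {}
    all_idx = np.arange(panel.size)
    subject_sites = set(som_idx) | set(germ_idx)
    bg_idx = np.array([i for i in all_idx if i not in subject_sites], dtype=int)
    for j, day in enumerate(clin.sample_days):
        sample_id = f"{subject_id}-P{j:02d}"
        depth = _depth(rng, config.depth_plasma_mean, config.depth_cv)
        tf = _tumor_fraction(tm, clin.arm, clin.tf0, clin.resistance_day, day)
        tf_by_sample[sample_id] = tf
        table: list[VariantCall] = []
        for i in som_idx:
            err = float(rng.beta(a_err, b_err))
            p = min(clonal[i] * tf + err, 0.999)
            alt = int(rng.binomial(depth, p))
            if alt >= 1:
                table.append(_make_call(panel, i, subject_id, sample_id, "plasma",
                                        depth, alt, hotspot_keys, synonymous[i]))
        for i in germ_idx:
            alt = int(rng.binomial(depth, min(germ_af[i], 0.999)))
            if alt >= 1:
                table.append(_make_call(panel, i, subject_id, sample_id,
                                        "plasma", depth, alt, hotspot_keys))
        rates = rng.beta(a_err, b_err, size=bg_idx.size)
        counts = rng.binomial(depth, rates)
        for i, k in zip(bg_idx, counts):
            if k >= 1:
                table.append(_make_call(panel, int(i), subject_id, sample_id,
                                        "plasma", depth, int(k), hotspot_keys))
                variant_labels.setdefault(panel.key(int(i)), "background")
        plasma_tables.append(table)
        sample_records.append(SampleRecord(
            subject_id=subject_id, sample_id=sample_id, sample_type="plasma",
            collection_day=day,
            input_mass_ng=float(np.clip(rng.lognormal(math.log(20), 0.4), 10, 50)),
            plasma_volume_ml=4.0,
        ))

    # --- clinical timeline (RECIST schedule, death, censoring)
    recist: list[tuple[int, str]] = []
    t = config.imaging_interval_days
    while t < clin.pfs_time:
        recist.append((t, "PR" if clin.arm == "responder" else "SD"))
        t += config.imaging_interval_days
    death_day: int | None = None
    last_imaging: int | None = None
    if clin.pfs_event and not clin.death:
        recist.append((clin.pfs_time, "PD"))
        last_imaging = clin.pfs_time
    elif clin.pfs_event and clin.death:
        death_day = clin.pfs_time
        last_imaging = recist[-1][0] if recist else None
    else:
        recist.append((clin.pfs_time, "SD"))
        last_imaging = clin.pfs_time

    truth = SubjectTruth(
        subject_id=subject_id, arm=clin.arm, variant_labels=variant_labels,
        tf_by_sample=tf_by_sample,
        molecular_progression_day=(int(round(clin.resistance_day))
                                   if clin.resistance_day is not None else None),
        pfs_time_days=clin.pfs_time, pfs_event=clin.pfs_event,
        ctdna_bearing=clin.bearing, hazard_ratio_true=config.hazard_ratio_true)
    clinical = ClinicalRecord(
        subject_id=subject_id, treatment_start_day=config.treatment_start_day,
        last_imaging_day=last_imaging, death_day=death_day)
    return SubjectSim(subject_id=subject_id, tissue_variants=tissue,
                      plasma_tables=plasma_tables, sample_records=sample_records,
                      clinical=clinical, recist_events=recist, truth=truth)


def _subject_seeds(config: CohortSimConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def simulate_cohort(
    config: CohortSimConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> CohortBundle:
    """Simulate the full cohort; optionally write the self-contained bundle.

    Identical (config, seed) produce an identical bundle; re-reading the
    written directory through the I/O layer reproduces the in-memory cohort.
    """
    panel = build_panel(config)
    subjects = []
    for k, seed in enumerate(_subject_seeds(config, config.n_subjects)):
        subjects.append(simulate_subject(config, seed,
                                         subject_id=f"S{k + 1:03d}", panel=panel))
    bundle = CohortBundle(config=config, panel=panel, subjects=subjects,
                          annotations=panel.annotations())
    if out_dir is not None:
        write_cohort(bundle, out_dir, overwrite=overwrite)
    return bundle


def simulate_survival_records(
    config: CohortSimConfig,
    seed: int | np.random.Generator,
):
    """Fast path: per-subject PFS outcomes and true ctDNA-bearing group only,
    drawn from the same clinical model as the full generator. Used for
    replicate-level recovery experiments (e.g. Cox coverage) where variant
    tables are not needed."""
    from .survival import CTDNA_NEGATIVE, CTDNA_POSITIVE, SurvivalRecord

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for k in range(config.n_subjects):
        clin = _simulate_subject_clinical(config, rng)
        records.append(SurvivalRecord(
            subject_id=f"S{k + 1:03d}", time_days=clin.pfs_time,
            event=clin.pfs_event,
            group=CTDNA_POSITIVE if clin.bearing else CTDNA_NEGATIVE))
    return records


def write_cohort(bundle: CohortBundle, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write every table of the bundle as the documented TSV/BED dialects."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    tissue = [v for s in bundle.subjects for v in s.tissue_variants]
    plasma = [v for s in bundle.subjects for table in s.plasma_tables for v in table]
    write_variant_table(tissue, out / "variants_tissue.tsv")
    write_variant_table(plasma, out / "variants_plasma.tsv")
    write_manifest([r for s in bundle.subjects for r in s.sample_records],
                   out / "manifest.tsv")
    write_clinical([s.clinical for s in bundle.subjects], out / "clinical.tsv")
    write_recist({s.subject_id: s.recist_events for s in bundle.subjects},
                 out / "recist.tsv")

    panel = bundle.panel
    with open(out / "mask.bed", "w") as fh:
        for chrom, start, end in panel.mask_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    with open(out / "hotspots.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for i in panel.hotspot_idx:
            chrom, pos, ref, alt = panel.key(i)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    for db, table in panel.pop_afs.items():
        with open(out / f"pop_{db}.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\taf\n")
            for i in sorted(table):
                chrom, pos, ref, alt = panel.key(i)
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{table[i]:.6f}\n")
    for db, table in panel.evidence.items():
        with open(out / f"somatic_{db}.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tcount\n")
            for i in sorted(table):
                chrom, pos, ref, alt = panel.key(i)
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{table[i]}\n")

    with open(out / "ground_truth_variants.tsv", "w") as fh:
        fh.write("subject_id\tchrom\tpos\tref\talt\tlabel\n")
        for s in bundle.subjects:
            for (chrom, pos, ref, alt), label in sorted(s.truth.variant_labels.items()):
                fh.write(f"{s.subject_id}\t{chrom}\t{pos}\t{ref}\t{alt}\t{label}\n")
    with open(out / "ground_truth_subjects.tsv", "w") as fh:
        fh.write("subject_id\tarm\tctdna_bearing\tmolecular_progression_day\t"
                 "pfs_time_days\tpfs_event\thazard_ratio_true\n")
        for s in bundle.subjects:
            t = s.truth
            mp = "" if t.molecular_progression_day is None else t.molecular_progression_day
            fh.write(f"{t.subject_id}\t{t.arm}\t{t.ctdna_bearing}\t{mp}\t"
                     f"{t.pfs_time_days}\t{t.pfs_event}\t{t.hazard_ratio_true}\n")
    with open(out / "ground_truth_samples.tsv", "w") as fh:
        fh.write("subject_id\tsample_id\ttrue_tumor_fraction\n")
        for s in bundle.subjects:
            for sample_id, tf in s.truth.tf_by_sample.items():
                fh.write(f"{s.subject_id}\t{sample_id}\t{tf:.8f}\n")
    bundle.config.to_yaml(out / "config.yaml")
    return out
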