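"""Reading, writing and validation of variant tables, manifests and annotations.

All genomic coordinates are 1-based and fully closed internally (the VCF
convention). BED input is 0-based half-open and converted on read. Variant
keys are normalized to a minimal left-aligned representation so that tissue
and plasma calls at the same site compare equal.

The native interchange format is a TSV dialect documented column-by-column
in ``docs/formats.md``; VCF v4.2 is supported for reading variant calls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantCall",
    "SampleRecord",
    "ClinicalRecord",
    "AnnotationTables",
    "VariantKey",
    "normalize_key",
    "read_variant_table",
    "write_variant_table",
    "read_manifest",
    "write_manifest",
    "read_clinical",
    "write_clinical",
    "read_recist",
    "write_recist",
    "load_annotations",
    "VariantTableError",
]

VariantKey = tuple[str, int, str, str]

SAMPLE_TYPES = ("tissue", "plasma")

VARIANT_COLUMNS = [
    "subject_id", "sample_id", "sample_type", "chrom", "pos", "ref", "alt",
    "depth", "alt_count", "af", "gene", "cds_change", "is_hotspot",
    "is_synonymous",
]

MANIFEST_COLUMNS = [
    "subject_id", "sample_id", "sample_type", "collection_day",
    "input_mass_ng", "plasma_volume_ml",
]

# Observed af must agree with alt_count/depth up to display rounding
# (3 significant decimals in percent notation).
_AF_ROUNDING_TOL = 5e-4

_ALLELE_CHARS = set("ACGT")


class VariantTableError(ValueError):
    """Malformed or invariant-violating row in a variant table."""


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Return the minimal left-aligned representation of an allele pair.

    Shared suffix bases are trimmed first, then shared prefix bases
    (advancing ``pos``), always retaining at least one base on each side.
    This makes indel keys from different callers comparable without a
    reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def _check_allele(allele: str) -> bool:
    return len(allele) > 0 and set(allele.upper()) <= _ALLELE_CHARS


@dataclass(slots=True)
class VariantCall:
    """One called alteration in one sample."""

    subject_id: str
    sample_id: str
    sample_type: str  # "tissue" | "plasma"
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int  # de-duplicated reads
    alt_count: int
    af: float
    gene: str = ""
    cds_change: str = ""
    is_hotspot: bool = False
    is_synonymous: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise VariantTableError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}")
        if self.pos < 1:
            raise VariantTableError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantTableError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not _check_allele(self.ref) or not _check_allele(self.alt):
            raise VariantTableError(
                f"alleles must be non-empty A/C/G/T strings, got {self.ref!r}>{self.alt!r}")
        if self.depth < 0 or self.alt_count < 0:
            raise VariantTableError("depth and alt_count must be non-negative")
        if self.alt_count > self.depth:
            raise VariantTableError(
                f"alt_count {self.alt_count} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}")
        if not 0.0 <= self.af <= 1.0:
            raise VariantTableError(f"af {self.af} outside [0, 1]")
        if self.depth > 0:
            expected = self.alt_count / self.depth
            if abs(self.af - expected) > _AF_ROUNDING_TOL:
                raise VariantTableError(
                    f"af {self.af} inconsistent with alt_count/depth = "
                    f"{expected:.6f} at {self.chrom}:{self.pos}")


@dataclass(slots=True)
class SampleRecord:
    """Manifest entry for one tissue or plasma sample."""

    subject_id: str
    sample_id: str
    sample_type: str
    collection_day: int  # days from histological diagnosis
    input_mass_ng: float
    plasma_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
        if self.collection_day < 0:
            raise ValueError(
                f"collection_day must be non-negative, got {self.collection_day} "
                f"for sample {self.sample_id}")
        if self.input_mass_ng <= 0:
            raise ValueError(f"input_mass_ng must be positive, got {self.input_mass_ng}")


@dataclass(slots=True)
class ClinicalRecord:
    """Per-subject clinical anchors (diagnosis is day 0 by convention)."""

    subject_id: str
    treatment_start_day: int
    last_imaging_day: int | None = None
    death_day: int | None = None


@dataclass
class AnnotationTables:
    """Population/somatic database annotations, region mask and hotspot list.

    ``pop_af_by_db`` maps database name (e.g. "exac", "dbsnp", "g1000") to
    per-key population allele frequencies; ``somatic_evidence`` holds summed
    COSMIC/TCGA-style evidence counts per key.
    """

    pop_af_by_db: dict[str, dict[VariantKey, float]] = field(default_factory=dict)
    somatic_evidence: dict[VariantKey, int] = field(default_factory=dict)
    region_mask: dict[str, IntervalTree] = field(default_factory=dict)
    hotspot_list: set[VariantKey] = field(default_factory=set)

    def pop_af(self, db: str, key: VariantKey) -> float:
        return self.pop_af_by_db.get(db, {}).get(key, 0.0)

    def max_pop_af(self, key: VariantKey) -> float:
        return max((t.get(key, 0.0) for t in self.pop_af_by_db.values()), default=0.0)

    def n_dbs_present(self, key: VariantKey) -> int:
        return sum(1 for t in self.pop_af_by_db.values() if key in t)

    def evidence_count(self, key: VariantKey) -> int:
        return self.somatic_evidence.get(key, 0)

    def is_masked(self, chrom: str, pos: int) -> bool:
        """Point membership query against the repetitive-region mask (1-based)."""
        tree = self.region_mask.get(chrom)
        return bool(tree is not None and tree[pos])

    def is_hotspot(self, key: VariantKey) -> bool:
        return key in self.hotspot_list


def _parse_bool(value: str, line_no: int) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "t", "yes"):
        return True
    if v in ("false", "0", "f", "no", ""):
        return False
    raise VariantTableError(f"line {line_no}: cannot parse boolean {value!r}")


def _variant_from_row(row: Mapping[str, str], line_no: int) -> VariantCall:
    try:
        return VariantCall(
            subject_id=str(row["subject_id"]),
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            depth=int(row["depth"]),
            alt_count=int(row["alt_count"]),
            af=float(row["af"]),
            gene=str(row.get("gene") or ""),
            cds_change=str(row.get("cds_change") or ""),
            is_hotspot=_parse_bool(row.get("is_hotspot", "false"), line_no),
            is_synonymous=_parse_bool(row.get("is_synonymous", "false"), line_no),
        )
    except VariantTableError as exc:
        raise VariantTableError(f"line {line_no}: {exc}") from exc
    except (KeyError, ValueError) as exc:
        raise VariantTableError(f"line {line_no}: malformed row ({exc})") from exc


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    variants: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(VARIANT_COLUMNS[:10]) - set(reader.fieldnames)
        if missing:
            raise VariantTableError(f"missing required columns: {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            variants.append(_variant_from_row(row, line_no))
    return variants


def _read_variant_vcf(
    path: Path,
    subject_id: str | None = None,
    sample_type: str = "plasma",
    af_key: str = "AF",
    gene_key: str = "GENE",
    cds_key: str = "CDS",
    hotspot_key: str = "HOTSPOT",
    synonymous_key: str = "SYN",
) -> list[VariantCall]:
    import pysam

    variants: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            sample_id = samples[0] if samples else Path(path).stem
            subj = subject_id
            if subj is None:
                subj = rec.info.get("SUBJECT", sample_id)
            info = dict(rec.info)
            for i, alt in enumerate(rec.alts or ()):
                if samples:
                    fmt = rec.samples[samples[0]]
                    depth = fmt.get("DP", info.get("DP", 0))
                    ad = fmt.get("AD")
                    alt_count = ad[i + 1] if ad is not None else 0
                    af_val = fmt.get(af_key, info.get(af_key))
                else:
                    depth = info.get("DP", 0)
                    ad = info.get("AD")
                    alt_count = ad[i] if isinstance(ad, tuple) else (ad or 0)
                    af_val = info.get(af_key)
                if isinstance(af_val, tuple):
                    af_val = af_val[i]
                if af_val is None:
                    af_val = alt_count / depth if depth else 0.0
                variants.append(VariantCall(
                    subject_id=str(subj),
                    sample_id=str(sample_id),
                    sample_type=sample_type,
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    depth=int(depth),
                    alt_count=int(alt_count),
                    af=float(af_val),
                    gene=str(info.get(gene_key, "") or ""),
                    cds_change=str(info.get(cds_key, "") or ""),
                    is_hotspot=bool(info.get(hotspot_key, False)),
                    is_synonymous=bool(info.get(synonymous_key, False)),
                ))
    return variants


def read_variant_table(path: str | Path, dialect: str = "tsv", **vcf_kwargs) -> list[VariantCall]:
    """Read a per-sample variant-call table.

    Parameters
    ----------
    path
        Input file. Must exist.
    dialect
        ``"tsv"`` for the native tab-separated dialect, ``"vcf"`` for VCF v4.2.
    vcf_kwargs
        For VCF input: ``subject_id``, ``sample_type`` and the INFO/FORMAT key
        names carrying allele frequency and annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, **vcf_kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variant_table(variants: Iterable[VariantCall], path: str | Path) -> None:
    """Write variants in the native TSV dialect (af to 6 decimals)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            writer.writerow([
                v.subject_id, v.sample_id, v.sample_type, v.chrom, v.pos,
                v.ref, v.alt, v.depth, v.alt_count, f"{v.af:.6f}", v.gene,
                v.cds_change, str(v.is_hotspot).lower(),
                str(v.is_synonymous).lower(),
            ])


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a sample manifest; records are stably sorted by subject then day."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "sample_id": str})
    required = {"subject_id", "sample_id", "sample_type", "collection_day", "input_mass_ng"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in manifest: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        vol = row.get("plasma_volume_ml")
        records.append(SampleRecord(
            subject_id=str(row["subject_id"]),
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            collection_day=int(row["collection_day"]),
            input_mass_ng=float(row["input_mass_ng"]),
            plasma_volume_ml=None if vol is None or pd.isna(vol) else float(vol),
        ))
    records.sort(key=lambda r: (r.subject_id, r.collection_day))
    return records


def write_manifest(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            vol = "" if r.plasma_volume_ml is None else f"{r.plasma_volume_ml:g}"
            writer.writerow([r.subject_id, r.sample_id, r.sample_type,
                             r.collection_day, f"{r.input_mass_ng:g}", vol])


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    records = []
    for _, row in df.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else int(v)
        records.append(ClinicalRecord(
            subject_id=str(row["subject_id"]),
            treatment_start_day=int(row["treatment_start_day"]),
            last_imaging_day=_opt("last_imaging_day"),
            death_day=_opt("death_day"),
        ))
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "treatment_start_day", "last_imaging_day", "death_day"])
        for r in records:
            writer.writerow([
                r.subject_id, r.treatment_start_day,
                "" if r.last_imaging_day is None else r.last_imaging_day,
                "" if r.death_day is None else r.death_day,
            ])


def read_recist(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Read RECIST assessments as subject_id -> ordered [(day, response)]."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    out: dict[str, list[tuple[int, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject_id"]), []).append(
            (int(row["day"]), str(row["response"])))
    for events in out.values():
        events.sort(key=lambda e: e[0])
    return out


def write_recist(events: Mapping[str, Sequence[tuple[int, str]]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "day", "response"])
        for subject_id in events:
            for day, response in events[subject_id]:
                writer.writerow([subject_id, day, response])


def _read_key_table(path: Path, value_col: str | None) -> dict[VariantKey, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    table: dict[VariantKey, float] = {}
    for _, row in df.iterrows():
        key = normalize_key(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        table[key] = float(row[value_col]) if value_col else 0.0
    return table


def _read_bed_mask(path: Path) -> dict[str, IntervalTree]:
    """Read a BED (0-based half-open) into per-chrom interval trees over
    1-based positions. Overlapping intervals are merged."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: BED line needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{line_no}: malformed interval {start} >= {end}")
            # BED [start, end) covers 1-based positions start+1 .. end,
            # i.e. half-open (start+1, end+1) on the 1-based axis.
            trees.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
    for tree in trees.values():
        tree.merge_overlaps(strict=False)
    return trees


def load_annotations(
    pop_tables: Mapping[str, str | Path] | None = None,
    somatic_tables: Mapping[str, str | Path] | None = None,
    mask_bed: str | Path | None = None,
    hotspot_path: str | Path | None = None,
) -> AnnotationTables:
    """Load population AF tables, somatic-evidence tables, the repetitive
    region mask and the hotspot whitelist into one annotation bundle.

    ``pop_tables`` / ``somatic_tables`` map a database role name ("exac",
    "dbsnp", "g1000", "cosmic", "tcga", ...) to a TSV with columns
    chrom/pos/ref/alt plus ``af`` (population tables) or ``count``
    (somatic-evidence tables).
    """
    ann = AnnotationTables()
    for db, path in (pop_tables or {}).items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        ann.pop_af_by_db[db] = _read_key_table(path, "af")
        for key, af in ann.pop_af_by_db[db].items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"population af {af} outside [0,1] in {path}")
    for db, path in (somatic_tables or {}).items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        for _, row in df.iterrows():
            key = normalize_key(str(row["chrom"]), int(row["pos"]),
                                str(row["ref"]), str(row["alt"]))
            count = int(row["count"])
            if count < 0:
                raise ValueError(f"negative evidence count in {path}")
            ann.somatic_evidence[key] = ann.somatic_evidence.get(key, 0) + count
    if mask_bed is not None:
        mask_bed = Path(mask_bed)
        if not mask_bed.exists():
            raise FileNotFoundError(mask_bed)
        ann.region_mask = _read_bed_mask(mask_bed)
    if hotspot_path is not None:
        hotspot_path = Path(hotspot_path)
        if not hotspot_path.exists():
            raise FileNotFoundError(hotspot_path)
        ann.hotspot_list = set(_read_key_table(hotspot_path, None).keys())
    return ann
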