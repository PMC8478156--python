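"""Domain types, file I/O and the variant-retention filter.

All coordinates are 0-based half-open in memory. On disk, SEG files follow
the usual 1-based inclusive convention and variant positions are 1-based;
the readers and writers convert. Every other module consumes the types
defined here.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CANCER_TYPES = ("CORE", "GAST", "PAAD", "GABI", "GIST")
STAGES = ("I", "II", "III", "IV", "unknown")
SEXES = ("M", "F", "unknown")
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "stop_gain",
    "fusion",
    "other",
)
ORIGINS = ("somatic", "germline")

#: classes counting toward mutation burden (substitutions + small indels;
#: fusions and "other" never count)
TMB_CLASSES = frozenset(
    {"missense", "nonsense", "stop_gain", "splice_site",
     "frameshift_indel", "inframe_indel"}
)

DEFAULT_MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "MLH3", "PMS1", "PMS2"})
DEFAULT_POL_GENES = frozenset({"POLE", "POLD1", "POLH"})


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    cancer_type: str
    primary_site: str | None = None
    stage: str = "unknown"
    age: float | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.cancer_type not in CANCER_TYPES:
            raise ValueError(
                f"unknown cancer_type {self.cancer_type!r}; "
                f"allowed: {', '.join(CANCER_TYPES)}"
            )


@dataclass(frozen=True)
class VariantCall:
    patient_id: str
    gene: str
    variant_class: str
    origin: str
    chrom: str
    pos: int  # 0-based internal
    vaf: float
    alt_reads_fwd: int
    alt_reads_rev: int
    in_target: bool = True
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.alt_reads_fwd < 0 or self.alt_reads_rev < 0:
            raise ValueError("negative supporting-read count")


@dataclass(frozen=True)
class CNSegment:
    patient_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    log2_ratio: float
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end {self.end} <= start {self.start} "
                f"({self.patient_id} {self.chrom})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MSILocusProfile:
    patient_id: str
    locus_id: str
    repeat_unit: str
    reference_repeat_len: int
    histogram: Mapping[int, int]  # observed repeat length (bp) -> read count

    def __post_init__(self) -> None:
        if self.reference_repeat_len < 15:
            raise ValueError("reference repeat length must be >= 15 bp")
        if any(c < 0 for c in self.histogram.values()):
            raise ValueError("negative read count in histogram")

    @property
    def depth(self) -> int:
        return sum(self.histogram.values())

    def modal_length(self) -> int | None:
        """Most frequent observed length; None for an empty histogram."""
        if not self.histogram or self.depth == 0:
            return None
        return max(self.histogram, key=lambda l: (self.histogram[l], -l))


@dataclass(frozen=True)
class MSILocusDef:
    locus_id: str
    chrom: str
    start: int
    repeat_unit: str
    reference_repeat_len: int


@dataclass
class GenePanel:
    """Targeted-panel description: gene content, pathway map, MSI loci.

    ``target_size_mb`` is the size of the coding target territory in
    megabases and is the TMB denominator.
    """

    genes: list[str]
    target_size_mb: float = 1.2
    pathway_map: dict[str, list[str]] = field(default_factory=dict)
    msi_loci: list[MSILocusDef] = field(default_factory=list)
    gene_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    mmr_genes: frozenset[str] = DEFAULT_MMR_GENES
    pol_genes: frozenset[str] = DEFAULT_POL_GENES
    name: str = "panel"

    def __post_init__(self) -> None:
        if self.target_size_mb <= 0:
            raise ValueError("target_size_mb must be positive")
        gene_set = set(self.genes)
        for gene in {g for gs in self.pathway_map.values() for g in gs}:
            if gene not in gene_set:
                raise ValueError(
                    f"pathway map references gene {gene!r} absent from panel"
                )

    @property
    def gene_to_pathways(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pw, members in self.pathway_map.items():
            for g in members:
                out.setdefault(g, []).append(pw)
        return out


@dataclass(frozen=True)
class ActionabilityRule:
    gene: str
    rule_type: str  # "protein_change" | "class"
    pattern: str


#: variant classes eligible for actionability matching
ACTIONABLE_CLASSES = frozenset(
    {"missense", "inframe_indel", "frameshift_indel", "splice_site",
     "stop_gain", "nonsense"}
)

_PROTEIN_PATTERN_RE = re.compile(r"^[A-Z]\d+[A-Za-z*]*$")


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_clinical(path: str | Path) -> list[PatientRecord]:
    """Read a clinical metadata TSV into patient records.

    Required columns: ``patient_id``, ``cancer_type``. Unknown stage/sex
    labels become ``unknown`` with a logged warning; an unknown cancer type
    or a duplicate patient id is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["patient_id", "cancer_type"], path)
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate patient_id(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        stage = row.get("stage", "") or "unknown"
        if stage not in STAGES:
            logger.warning("patient %s: unknown stage %r mapped to 'unknown'",
                           row["patient_id"], stage)
            stage = "unknown"
        sex = row.get("sex", "") or "unknown"
        if sex not in SEXES:
            logger.warning("patient %s: unknown sex %r mapped to 'unknown'",
                           row["patient_id"], sex)
            sex = "unknown"
        age_raw = row.get("age", "")
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                cancer_type=row["cancer_type"],
                primary_site=row.get("primary_site", "") or None,
                stage=stage,
                age=float(age_raw) if age_raw else None,
                sex=sex,
            )
        )
    return records


def write_clinical(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "cancer_type": r.cancer_type,
            "primary_site": r.primary_site or "",
            "stage": r.stage,
            "age": "" if r.age is None else r.age,
            "sex": r.sex,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_VARIANT_COLUMNS = [
    "patient_id", "gene", "variant_class", "origin", "chrom", "pos",
    "protein_change", "vaf", "alt_reads_fwd", "alt_reads_rev", "in_target",
]


def read_variant_table(path: str | Path, vaf_unit: str = "fraction") -> list[VariantCall]:
    """Read a MAF-like variant TSV.

    ``vaf_unit`` declares the dialect of the vaf column: ``"fraction"``
    (0–1) or ``"percent"`` (0–100). Positions on disk are 1-based.
    """
    if vaf_unit not in ("fraction", "percent"):
        raise ValueError("vaf_unit must be 'fraction' or 'percent'")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, [c for c in _VARIANT_COLUMNS if c != "protein_change"], path)
    out = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            vaf = float(row["vaf"])
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: unparseable vaf "
                             f"{row['vaf']!r}") from exc
        if vaf_unit == "percent":
            vaf /= 100.0
        fwd, rev = int(row["alt_reads_fwd"]), int(row["alt_reads_rev"])
        if fwd < 0 or rev < 0:
            raise ValueError(f"{path}: line {line_no}: negative read count")
        try:
            out.append(
                VariantCall(
                    patient_id=row["patient_id"],
                    gene=row["gene"],
                    variant_class=row["variant_class"],
                    origin=row["origin"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]) - 1,
                    protein_change=row.get("protein_change", "") or None,
                    vaf=vaf,
                    alt_reads_fwd=fwd,
                    alt_reads_rev=rev,
                    in_target=str(row["in_target"]).strip().lower()
                    in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return out


def write_variant_table(variants: Iterable[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "patient_id": v.patient_id,
            "gene": v.gene,
            "variant_class": v.variant_class,
            "origin": v.origin,
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "protein_change": v.protein_change or "",
            "vaf": f"{v.vaf:.6g}",
            "alt_reads_fwd": v.alt_reads_fwd,
            "alt_reads_rev": v.alt_reads_rev,
            "in_target": v.in_target,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[CNSegment]:
    """Read a standard 6-column SEG file (1-based inclusive on disk).

    Coordinates become 0-based half-open internally; overlapping segments
    for one patient/chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected 6 SEG columns, got {df.shape[1]}")
    df.columns = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    segments = []
    for _, row in df.iterrows():
        start, end = int(row["loc.start"]), int(row["loc.end"])
        if end < start:
            raise ValueError(
                f"{path}: segment end {end} < start {start} for {row['ID']}"
            )
        n_probes = None if pd.isna(row["num.mark"]) else int(row["num.mark"])
        segments.append(
            CNSegment(
                patient_id=str(row["ID"]),
                chrom=str(row["chrom"]),
                start=start - 1,
                end=end,
                log2_ratio=float(row["seg.mean"]),
                n_probes=n_probes,
            )
        )
    _check_no_overlap(segments, path)
    return segments


def _check_no_overlap(segments: Sequence[CNSegment], path: str | Path) -> None:
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for s in segments:
        by_key.setdefault((s.patient_id, s.chrom), []).append(s)
    for (pid, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{path}: overlapping segments for {pid} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_seg(segments: Iterable[CNSegment], path: str | Path) -> None:
    rows = [
        {
            "ID": s.patient_id,
            "chrom": s.chrom,
            "loc.start": s.start + 1,
            "loc.end": s.end,
            "num.mark": "" if s.n_probes is None else s.n_probes,
            "seg.mean": f"{s.log2_ratio:.6g}",
        }
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def read_msi_profiles(path: str | Path, panel: GenePanel) -> list[MSILocusProfile]:
    """Read a long-format MSI TSV (patient_id, locus_id, repeat_len, read_count)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["patient_id", "locus_id", "repeat_len", "read_count"], path)
    locus_defs = {l.locus_id: l for l in panel.msi_loci}
    profiles = []
    for (pid, locus_id), grp in df.groupby(["patient_id", "locus_id"], sort=False):
        if locus_id not in locus_defs:
            raise ValueError(f"{path}: locus {locus_id!r} not in panel")
        ldef = locus_defs[locus_id]
        hist = {
            int(l): int(c)
            for l, c in zip(grp["repeat_len"], grp["read_count"])
            if int(c) > 0
        }
        profiles.append(
            MSILocusProfile(
                patient_id=str(pid),
                locus_id=str(locus_id),
                repeat_unit=ldef.repeat_unit,
                reference_repeat_len=ldef.reference_repeat_len,
                histogram=hist,
            )
        )
    return profiles


def write_msi_profiles(profiles: Iterable[MSILocusProfile], path: str | Path) -> None:
    rows = [
        {"patient_id": p.patient_id, "locus_id": p.locus_id,
         "repeat_len": l, "read_count": c}
        for p in profiles
        for l, c in sorted(p.histogram.items())
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "locus_id", "repeat_len", "read_count"]
    ).to_csv(path, sep="\t", index=False)


def read_panel_config(path: str | Path) -> GenePanel:
    """Load a YAML panel configuration; omitted fields take defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    loci = [
        MSILocusDef(
            locus_id=d["locus_id"],
            chrom=d["chrom"],
            start=int(d["start"]),
            repeat_unit=d["repeat_unit"],
            reference_repeat_len=int(d["reference_repeat_len"]),
        )
        for d in cfg.get("msi_loci", [])
    ]
    return GenePanel(
        genes=list(cfg["genes"]),
        target_size_mb=float(cfg.get("target_size_mb", 1.2)),
        pathway_map={k: list(v) for k, v in cfg.get("pathways", {}).items()},
        msi_loci=loci,
        gene_intervals={
            g: (str(c), int(s), int(e))
            for g, (c, s, e) in cfg.get("gene_intervals", {}).items()
        },
        chrom_lengths={k: int(v) for k, v in cfg.get("chrom_lengths", {}).items()},
        mmr_genes=frozenset(cfg.get("mmr_genes", DEFAULT_MMR_GENES)),
        pol_genes=frozenset(cfg.get("pol_genes", DEFAULT_POL_GENES)),
        name=cfg.get("name", "panel"),
    )


def default_panel() -> GenePanel:
    """The bundled synthetic 416-gene default panel."""
    ref = resources.files("gilandscape.data") / "default_panel_synthetic.yaml"
    with resources.as_file(ref) as p:
        return read_panel_config(p)


def load_actionability(path: str | Path) -> list[ActionabilityRule]:
    """Load a drug-evidence lookup table (gene, rule_type, pattern)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene", "rule_type", "pattern"], path)
    if df.empty:
        raise ValueError(f"{path}: actionability table has no rows")
    rules = []
    for _, row in df.iterrows():
        rt, pat = row["rule_type"], row["pattern"]
        if rt == "class":
            if pat not in VARIANT_CLASSES:
                raise ValueError(f"{path}: malformed class rule {pat!r}")
        elif rt == "protein_change":
            if not _PROTEIN_PATTERN_RE.match(pat):
                raise ValueError(f"{path}: malformed protein pattern {pat!r}")
        else:
            raise ValueError(f"{path}: unknown rule_type {rt!r}")
        rules.append(ActionabilityRule(gene=row["gene"], rule_type=rt, pattern=pat))
    return rules


def default_actionability() -> list[ActionabilityRule]:
    ref = resources.files("gilandscape.data") / "actionability_synthetic.tsv"
    with resources.as_file(ref) as p:
        return load_actionability(p)


# ---------------------------------------------------------------------------
# the retention filter


def filter_variants(
    variants: Iterable[VariantCall],
    min_vaf: float = 0.01,
    min_reads_per_strand: int = 3,
) -> list[VariantCall]:
    """Apply the somatic variant-retention filter.

    A somatic call is kept when its allele frequency is at least ``min_vaf``
    and it has at least ``min_reads_per_strand`` supporting reads on each
    strand (thresholds inclusive). Germline records pass through unchanged;
    input order is preserved.
    """
    kept = []
    for v in variants:
        if v.origin == "germline":
            kept.append(v)
        elif (
            v.vaf >= min_vaf
            and v.alt_reads_fwd >= min_reads_per_strand
            and v.alt_reads_rev >= min_reads_per_strand
        ):
            kept.append(v)
    return kept
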