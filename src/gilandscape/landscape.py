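"""Mutation-landscape matrices, gene/pathway frequencies and CNV calls.

Everything downstream of the instability metrics works off a binary
patient x feature alteration matrix: gene frequency tables, pathway
alteration fractions, gene-level copy-number calls from segments,
actionability annotation and MMR/POL mutation burden.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import (
    ACTIONABLE_CLASSES,
    ActionabilityRule,
    CNSegment,
    GenePanel,
    PatientRecord,
    VariantCall,
)

logger = logging.getLogger(__name__)


def percent(n: int, d: int) -> int:
    """Integer display percentage, rounding half away from zero."""
    if d == 0:
        raise ValueError("zero denominator")
    x = 100.0 * n / d
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class CohortMatrix:
    """Binary patient x feature alteration matrix with cell provenance.

    ``values`` is a boolean DataFrame (patients x features); ``provenance``
    is a parallel string DataFrame whose cells hold a ``+``-joined subset of
    {mutation, cnv, fusion}, empty when unaltered.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneCNVCall:
    patient_id: str
    gene: str
    call: str  # gain | loss | neutral
    mean_log2: float | None
    covered_fraction: float


def build_alteration_matrix(
    variants: Sequence[VariantCall],
    patients: Sequence[PatientRecord],
    panel: GenePanel,
    cnv_calls: Sequence[GeneCNVCall] | None = None,
    fusions_included: bool = True,
) -> CohortMatrix:
    """Binary somatic-alteration matrix over the whole cohort.

    A cell is set when the patient carries at least one somatic small
    variant in the gene, a fusion (when enabled), or — when CNV calls are
    passed — a non-neutral gene-level copy-number call. Germline records
    never set cells. Every clinical patient appears even if all-zero;
    variants in genes outside the panel are kept under their own symbol
    with a warning.
    """
    pids = [p.patient_id for p in patients]
    panel_genes = set(panel.genes)
    marks: dict[tuple[str, str], set[str]] = {}
    genes_seen: list[str] = []

    def mark(pid: str, gene: str, kind: str) -> None:
        if gene not in panel_genes and gene not in genes_seen:
            logger.warning("gene %s not in panel; included under its own symbol",
                           gene)
        if gene not in genes_seen:
            genes_seen.append(gene)
        marks.setdefault((pid, gene), set()).add(kind)

    pid_set = set(pids)
    for v in variants:
        if v.origin != "somatic" or v.patient_id not in pid_set:
            continue
        if v.variant_class == "fusion":
            if fusions_included:
                mark(v.patient_id, v.gene, "fusion")
        elif v.variant_class != "other":
            mark(v.patient_id, v.gene, "mutation")
    for call in cnv_calls or ():
        if call.call != "neutral" and call.patient_id in pid_set:
            mark(call.patient_id, call.gene, "cnv")

    genes = sorted(genes_seen)
    values = pd.DataFrame(False, index=pids, columns=genes, dtype=bool)
    prov = pd.DataFrame("", index=pids, columns=genes, dtype=object)
    order = ("mutation", "cnv", "fusion")
    for (pid, gene), kinds in marks.items():
        values.at[pid, gene] = True
        prov.at[pid, gene] = "+".join(k for k in order if k in kinds)
    return CohortMatrix(values=values, provenance=prov)


def gene_frequencies(
    matrix: CohortMatrix, grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-group alteration frequency of every feature.

    Returns a long table (group, gene, n_altered, n_group, frequency, pct)
    with pct rounded half away from zero for display. Without a grouping,
    a single "all" group covers the cohort.
    """
    if grouping is None:
        grouping = {pid: "all" for pid in matrix.patients}
    members: dict[str, list[str]] = {}
    for pid in matrix.patients:
        g = grouping.get(pid)
        if g is not None:
            members.setdefault(g, []).append(pid)
    rows = []
    for group in sorted(members):
        pids = members[group]
        if not pids:
            logger.warning("group %r empty; dropped", group)
            continue
        counts = matrix.values.loc[pids].sum(axis=0)
        for gene in matrix.features:
            n_alt = int(counts[gene])
            rows.append(
                dict(group=group, gene=gene, n_altered=n_alt, n_group=len(pids),
                     frequency=n_alt / len(pids), pct=percent(n_alt, len(pids)))
            )
    return pd.DataFrame(rows)


def pathway_alteration_fraction(
    matrix: CohortMatrix,
    pathway_map: Mapping[str, Sequence[str]],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group fraction of patients with >= 1 altered gene per pathway.

    Pathways with no member gene present in the matrix are reported with a
    missing fraction.
    """
    if not pathway_map:
        raise ValueError("pathway map is empty")
    if grouping is None:
        grouping = {pid: "all" for pid in matrix.patients}
    members: dict[str, list[str]] = {}
    for pid in matrix.patients:
        g = grouping.get(pid)
        if g is not None:
            members.setdefault(g, []).append(pid)
    feature_set = set(matrix.features)
    rows = []
    for group in sorted(members):
        pids = members[group]
        if not pids:
            continue
        sub = matrix.values.loc[pids]
        for pw, genes in pathway_map.items():
            present = [g for g in genes if g in feature_set]
            if not present:
                rows.append(dict(group=group, pathway=pw, n_altered=None,
                                 n_group=len(pids), fraction=None, pct=None))
                continue
            n_alt = int(sub[present].any(axis=1).sum())
            rows.append(
                dict(group=group, pathway=pw, n_altered=n_alt, n_group=len(pids),
                     fraction=n_alt / len(pids), pct=percent(n_alt, len(pids)))
            )
    return pd.DataFrame(rows)


def call_gene_cnv(
    segments: Sequence[CNSegment],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    gain_cutoff: float = 0.2,
    loss_cutoff: float = -0.2,
    min_overlap: float = 0.5,
) -> list[GeneCNVCall]:
    """Threshold gene-level CNV calls from copy-number segments.

    Per patient and gene, the log2 ratios of overlapping segments are
    averaged weighted by overlap length; the call is gain above
    ``gain_cutoff``, loss below ``loss_cutoff``, neutral otherwise — and
    neutral whenever less than ``min_overlap`` of the gene interval is
    covered by segments.
    """
    by_pat_chrom: dict[tuple[str, str], list[CNSegment]] = {}
    patients: list[str] = []
    for s in segments:
        if s.patient_id not in patients:
            patients.append(s.patient_id)
        by_pat_chrom.setdefault((s.patient_id, s.chrom), []).append(s)

    calls = []
    warned_chroms: set[tuple[str, str]] = set()
    for pid in patients:
        for gene, (chrom, gstart, gend) in gene_intervals.items():
            segs = by_pat_chrom.get((pid, chrom))
            if segs is None:
                if (pid, chrom) not in warned_chroms:
                    logger.warning(
                        "patient %s: no segments on %s; genes there neutral",
                        pid, chrom)
                    warned_chroms.add((pid, chrom))
                calls.append(GeneCNVCall(pid, gene, "neutral", None, 0.0))
                continue
            covered = 0
            weighted = 0.0
            for s in segs:
                ov = min(s.end, gend) - max(s.start, gstart)
                if ov > 0:
                    covered += ov
                    weighted += ov * s.log2_ratio
            frac = covered / (gend - gstart)
            if covered == 0 or frac < min_overlap:
                calls.append(GeneCNVCall(pid, gene, "neutral",
                                         weighted / covered if covered else None,
                                         frac))
                continue
            mean_log2 = weighted / covered
            if mean_log2 > gain_cutoff:
                call = "gain"
            elif mean_log2 < loss_cutoff:
                call = "loss"
            else:
                call = "neutral"
            calls.append(GeneCNVCall(pid, gene, call, mean_log2, frac))
    return calls


def cnv_calls_to_frame(calls: Sequence[GeneCNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"patient_id": c.patient_id, "gene": c.gene, "call": c.call,
             "mean_log2": c.mean_log2, "covered_fraction": c.covered_fraction}
            for c in calls
        ]
    )


def _normalize_protein_change(pc: str) -> str:
    pc = pc.strip()
    return pc[2:] if pc.startswith("p.") else pc


def annotate_actionable(
    variants: Sequence[VariantCall],
    rules: Sequence[ActionabilityRule],
    patients: Sequence[PatientRecord] | None = None,
) -> tuple[dict[str, bool], pd.DataFrame]:
    """Flag patients carrying >= 1 actionable somatic variant.

    Protein-change rules match the residue prefix of the normalized change
    (``G12`` hits p.G12D); class rules match the variant class. Only
    somatic variants of actionable classes (missense, indels, splice-site,
    stop-gain/nonsense) are eligible. Returns the per-patient flags and a
    table of matched variants.
    """
    if not rules:
        raise ValueError("actionability table is empty")
    flags: dict[str, bool] = (
        {p.patient_id: False for p in patients} if patients else {}
    )
    matched = []
    for v in variants:
        flags.setdefault(v.patient_id, False)
        if v.origin != "somatic" or v.variant_class not in ACTIONABLE_CLASSES:
            continue
        for rule in rules:
            if rule.gene != v.gene:
                continue
            if rule.rule_type == "class":
                hit = v.variant_class == rule.pattern
            else:
                pc = _normalize_protein_change(v.protein_change or "")
                hit = bool(pc) and pc.startswith(rule.pattern)
            if hit:
                flags[v.patient_id] = True
                matched.append(
                    dict(patient_id=v.patient_id, gene=v.gene,
                         variant_class=v.variant_class,
                         protein_change=v.protein_change or "",
                         rule_type=rule.rule_type, pattern=rule.pattern)
                )
                break
    return flags, pd.DataFrame(
        matched, columns=["patient_id", "gene", "variant_class",
                          "protein_change", "rule_type", "pattern"]
    )


def mmr_pol_burden(
    variants: Iterable[VariantCall],
    panel: GenePanel,
    patients: Sequence[PatientRecord] | None = None,
) -> pd.DataFrame:
    """Per-patient count of somatic + germline variants in MMR/POL genes.

    Germline carriers count: defects in mismatch repair or replicative
    polymerases drive hyper-mutation regardless of origin. Returns columns
    patient_id, n_mmr_pol, n_somatic, n_germline, has_any.
    """
    target = panel.mmr_genes | panel.pol_genes
    counts: dict[str, dict[str, int]] = {}
    if patients:
        for p in patients:
            counts[p.patient_id] = {"somatic": 0, "germline": 0}
    for v in variants:
        c = counts.setdefault(v.patient_id, {"somatic": 0, "germline": 0})
        if v.gene in target and v.variant_class not in ("fusion", "other"):
            c[v.origin] += 1
    rows = [
        dict(patient_id=pid, n_mmr_pol=c["somatic"] + c["germline"],
             n_somatic=c["somatic"], n_germline=c["germline"],
             has_any=(c["somatic"] + c["germline"]) >= 1)
        for pid, c in counts.items()
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "n_mmr_pol", "n_somatic", "n_germline",
                       "has_any"]
    )
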