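"""Genomic-instability metrics: TMB, MSI calling and CIN scoring.

Three per-tumor markers computed from targeted-panel data:

* **TMB** — somatic base substitutions and small indels inside the target
  territory per megabase of coding target; tumors with TMB strictly above
  20 mut/Mb are flagged hyper-mutated.
* **MSI** — per-locus read-length histograms at mononucleotide repeats are
  compared against a baseline built from a pool of stable samples; a tumor
  is MSI when more than 45% of its qualified loci are unstable.
* **CIN** — the length-weighted fraction of the covered genome lying in
  copy-number segments with \\|log2 ratio\\| above 0.2; cohort-wide upper and
  lower quartiles define the high- and low-CIN groups.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import (
    CNSegment,
    GenePanel,
    MSILocusProfile,
    PatientRecord,
    TMB_CLASSES,
    VariantCall,
)

logger = logging.getLogger(__name__)

HYPERMUTATION_TMB_THRESHOLD = 20.0
CIN_LOG2_CUTOFF = 0.2
MSI_SITE_FRACTION = 0.45


@dataclass
class InstabilityMetrics:
    patient_id: str
    tmb: float
    hypermutated: bool
    cin_score: float | None  # None when not evaluable
    cin_group: str = "not_evaluable"  # high | mid | low | not_evaluable
    msi_status: str = "not_evaluable"  # MSI | MSS | not_evaluable
    n_qualified_sites: int = 0
    n_unstable_sites: int = 0


@dataclass
class BaselineLocus:
    frequencies: dict[int, float]  # repeat length -> pooled frequency
    support: frozenset[int]  # lengths with pooled frequency >= floor
    n_samples: int


@dataclass
class MSIBaseline:
    """Pooled reference length distributions from stable samples."""

    loci: dict[str, BaselineLocus] = field(default_factory=dict)
    n_pool_samples: int = 0


# ---------------------------------------------------------------------------
# TMB


def compute_tmb(variants: Iterable[VariantCall], panel: GenePanel) -> float:
    """Mutations per megabase for one patient's filtered somatic calls.

    Counts somatic, in-target substitutions and small indels (missense,
    nonsense, stop-gain, splice-site, frameshift and in-frame indels);
    fusions and germline records never count.
    """
    if panel.target_size_mb <= 0:
        raise ValueError("panel target size must be positive")
    n = sum(
        1
        for v in variants
        if v.origin == "somatic" and v.in_target and v.variant_class in TMB_CLASSES
    )
    return n / panel.target_size_mb


def classify_hypermutated(
    tmb: float, threshold: float = HYPERMUTATION_TMB_THRESHOLD
) -> bool:
    """True iff TMB strictly exceeds the hyper-mutation threshold."""
    return tmb > threshold


# ---------------------------------------------------------------------------
# CIN


def compute_cin_score(
    segments: Sequence[CNSegment], log2_cutoff: float = CIN_LOG2_CUTOFF
) -> float | None:
    """Length-weighted fraction of covered genome with aberrant copy number.

    A segment is aberrant when its log2 ratio is below ``-log2_cutoff`` or
    above ``+log2_cutoff``. Returns None (not evaluable) for an empty
    segment list rather than 0.
    """
    total = sum(s.length for s in segments)
    if total == 0:
        return None
    aberrant = sum(s.length for s in segments if abs(s.log2_ratio) > log2_cutoff)
    return aberrant / total


def classify_cin_groups(scores: Mapping[str, float | None]) -> dict[str, str]:
    """Assign high/mid/low CIN groups by pooled-cohort quartiles.

    The extreme groups hold ``floor(n/4)`` patients each (nearest-rank
    cutoffs on the pooled evaluable scores). A score tied at both cutoffs
    (e.g. a constant cohort) falls into neither extreme and is mid. Fewer
    than 4 evaluable scores leaves everyone not_evaluable.
    """
    evaluable = {p: s for p, s in scores.items() if s is not None}
    out = {p: "not_evaluable" for p in scores}
    if len(evaluable) < 4:
        if evaluable:
            logger.warning(
                "only %d evaluable CIN scores; need >= 4 for quartile groups",
                len(evaluable),
            )
        return out
    ordered = sorted(evaluable.values())
    k = len(ordered) // 4
    low_cut = ordered[k - 1]
    high_cut = ordered[-k]
    for pid, s in evaluable.items():
        if s >= high_cut and s > low_cut:
            out[pid] = "high"
        elif s <= low_cut and s < high_cut:
            out[pid] = "low"
        else:
            out[pid] = "mid"
    return out


# ---------------------------------------------------------------------------
# MSI


def build_msi_baseline(
    profiles: Iterable[MSILocusProfile],
    panel: GenePanel,
    min_samples: int = 5,
    support_floor: float = 0.01,
) -> MSIBaseline:
    """Pool stable-sample histograms into per-locus baseline distributions.

    Per locus, read counts from all contributing samples (those with
    non-zero depth there) are summed and normalized; the support set is
    every length holding at least ``support_floor`` of the pooled mass.
    Loci observed in no sample are dropped with a warning.
    """
    by_locus: dict[str, list[MSILocusProfile]] = {}
    pool_ids = set()
    for p in profiles:
        pool_ids.add(p.patient_id)
        if p.depth > 0:
            by_locus.setdefault(p.locus_id, []).append(p)
    if len(pool_ids) < min_samples:
        raise ValueError(
            f"baseline pool has {len(pool_ids)} samples; need >= {min_samples}"
        )
    baseline = MSIBaseline(n_pool_samples=len(pool_ids))
    for locus in panel.msi_loci:
        contributing = by_locus.get(locus.locus_id, [])
        if not contributing:
            logger.warning("locus %s absent from every baseline sample; dropped",
                           locus.locus_id)
            continue
        pooled: dict[int, int] = {}
        for p in contributing:
            for length, count in p.histogram.items():
                pooled[length] = pooled.get(length, 0) + count
        depth = sum(pooled.values())
        freqs = {l: c / depth for l, c in pooled.items()}
        support = frozenset(l for l, f in freqs.items() if f >= support_floor)
        baseline.loci[locus.locus_id] = BaselineLocus(
            frequencies=freqs,
            support=support,
            n_samples=len({p.patient_id for p in contributing}),
        )
    return baseline


def score_locus_instability(
    profile: MSILocusProfile,
    baseline: MSIBaseline,
    min_depth: int = 20,
    unstable_mass_cutoff: float = 0.2,
) -> str:
    """Classify one locus as stable / unstable / unqualified.

    Unqualified below ``min_depth`` or when the locus has no baseline;
    otherwise unstable iff the fraction of reads at lengths outside the
    baseline support set reaches ``unstable_mass_cutoff``.
    """
    entry = baseline.loci.get(profile.locus_id)
    if entry is None:
        return "unqualified"
    depth = profile.depth
    if depth < min_depth:
        return "unqualified"
    out_of_support = sum(
        c for l, c in profile.histogram.items() if l not in entry.support
    )
    return "unstable" if out_of_support / depth >= unstable_mass_cutoff else "stable"


def call_msi(
    profiles: Iterable[MSILocusProfile],
    baseline: MSIBaseline,
    site_fraction: float = MSI_SITE_FRACTION,
    min_qualified: int = 10,
    min_depth: int = 20,
    unstable_mass_cutoff: float = 0.2,
) -> tuple[str, int, int]:
    """Sample-level MSI call from one patient's locus profiles.

    Returns ``(status, n_qualified, n_unstable)``. The sample is MSI when
    strictly more than ``site_fraction`` of qualified loci are unstable,
    and not evaluable with fewer than ``min_qualified`` qualified loci.
    """
    n_qualified = n_unstable = 0
    for p in profiles:
        verdict = score_locus_instability(
            p, baseline, min_depth=min_depth,
            unstable_mass_cutoff=unstable_mass_cutoff,
        )
        if verdict == "unqualified":
            continue
        n_qualified += 1
        if verdict == "unstable":
            n_unstable += 1
    if n_qualified < min_qualified:
        return "not_evaluable", n_qualified, n_unstable
    status = "MSI" if n_unstable / n_qualified > site_fraction else "MSS"
    return status, n_qualified, n_unstable


def select_baseline_pool(
    profiles_by_patient: Mapping[str, Sequence[MSILocusProfile]],
    min_modal_match: float = 0.8,
) -> list[str]:
    """Pick self-consistent stable samples to seed the baseline pool.

    Without matched normals, samples whose modal repeat length equals the
    panel reference at a large fraction of loci (default 80%) act as the
    stable pool — unstable tumors shift the mode at many loci and are
    excluded.
    """
    pool = []
    for pid, profiles in profiles_by_patient.items():
        informative = [p for p in profiles if p.depth > 0]
        if not informative:
            continue
        n_match = sum(
            1 for p in informative if p.modal_length() == p.reference_repeat_len
        )
        if n_match / len(informative) >= min_modal_match:
            pool.append(pid)
    return pool


# ---------------------------------------------------------------------------
# cohort-level driver


def compute_cohort_metrics(
    patients: Sequence[PatientRecord],
    filtered_variants: Sequence[VariantCall],
    segments: Sequence[CNSegment],
    msi_profiles: Sequence[MSILocusProfile],
    panel: GenePanel,
    baseline: MSIBaseline | None = None,
) -> list[InstabilityMetrics]:
    """Per-patient instability metrics across a cohort.

    When no MSI baseline is supplied one is built from a self-selected
    stable pool (see :func:`select_baseline_pool`). CIN groups are assigned
    by quartiles pooled over all evaluable tumors.
    """
    var_by_pat: dict[str, list[VariantCall]] = {p.patient_id: [] for p in patients}
    for v in filtered_variants:
        var_by_pat.setdefault(v.patient_id, []).append(v)
    seg_by_pat: dict[str, list[CNSegment]] = {}
    for s in segments:
        seg_by_pat.setdefault(s.patient_id, []).append(s)
    msi_by_pat: dict[str, list[MSILocusProfile]] = {}
    for p in msi_profiles:
        msi_by_pat.setdefault(p.patient_id, []).append(p)

    if baseline is None and msi_by_pat:
        pool_ids = select_baseline_pool(msi_by_pat)
        pool_profiles = [p for pid in pool_ids for p in msi_by_pat[pid]]
        baseline = build_msi_baseline(pool_profiles, panel)

    metrics = []
    for rec in patients:
        pid = rec.patient_id
        tmb = compute_tmb(var_by_pat.get(pid, []), panel)
        cin = compute_cin_score(seg_by_pat.get(pid, []))
        if baseline is not None and pid in msi_by_pat:
            status, n_q, n_u = call_msi(msi_by_pat[pid], baseline)
        else:
            status, n_q, n_u = "not_evaluable", 0, 0
        metrics.append(
            InstabilityMetrics(
                patient_id=pid,
                tmb=tmb,
                hypermutated=classify_hypermutated(tmb),
                cin_score=cin,
                msi_status=status,
                n_qualified_sites=n_q,
                n_unstable_sites=n_u,
            )
        )
    groups = classify_cin_groups({m.patient_id: m.cin_score for m in metrics})
    for m in metrics:
        m.cin_group = groups[m.patient_id]
    return metrics


def metrics_to_frame(metrics: Sequence[InstabilityMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "tmb": m.tmb,
                "hypermutated": m.hypermutated,
                "cin_score": "" if m.cin_score is None else m.cin_score,
                "cin_group": m.cin_group,
                "msi_status": m.msi_status,
                "n_qualified_sites": m.n_qualified_sites,
                "n_unstable_sites": m.n_unstable_sites,
            }
            for m in metrics
        ]
    )
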