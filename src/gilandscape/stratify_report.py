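"""Anatomical/MSI stratification and the end-to-end report pipeline.

Colorectal tumors split anatomically at the transverse colon: the proximal
two-thirds of the transverse colon, the ascending colon and the cecum are
right-sided; the distal third, descending colon, sigmoid and rectum are
left-sided. Gastric tumors group into cardia, fundus/body and
pylorus/duodenum. MSI status takes precedence: an MSI tumor is its own
stratum and never carries a side or region label.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .core_model import (
    PatientRecord,
    default_actionability,
    default_panel,
    filter_variants,
    write_clinical,
    write_msi_profiles,
    write_seg,
    write_variant_table,
)
from .instability import InstabilityMetrics, compute_cohort_metrics, metrics_to_frame
from .landscape import (
    annotate_actionable,
    build_alteration_matrix,
    call_gene_cnv,
    cnv_calls_to_frame,
    gene_frequencies,
    mmr_pol_burden,
    pathway_alteration_fraction,
)
from .stats import (
    compare_to_reference,
    dunn_posthoc,
    kruskal_wallis,
    pairwise_group_test,
    read_reference_counts,
)
from .synthetic_cohort import CohortSimParams, default_sim_params, generate_cohort

logger = logging.getLogger(__name__)

# user-extensible synonym tables
COLORECTAL_RIGHT_SITES = frozenset({
    "cecum", "ascending colon", "hepatic flexure",
    "transverse colon proximal", "proximal transverse colon",
})
COLORECTAL_LEFT_SITES = frozenset({
    "descending colon", "sigmoid", "sigmoid colon", "rectum", "rectosigmoid",
    "splenic flexure", "transverse colon distal", "distal transverse colon",
})
GASTRIC_REGION_SITES: dict[str, frozenset[str]] = {
    "cardia": frozenset({"cardia", "gastric cardia", "gastroesophageal junction"}),
    "fundus_body": frozenset({"fundus", "body", "gastric body", "fundus and body",
                              "greater curvature", "lesser curvature"}),
    "pylorus_duodenum": frozenset({"pylorus", "antrum", "pyloric antrum",
                                   "duodenum", "pylorus and duodenum"}),
}


@dataclass(frozen=True)
class StratumLabel:
    patient_id: str
    scheme: str  # "CORE" | "GAST" | "none"
    stratum: str


def map_colorectal_side(primary_site: str | None) -> str:
    """Map a colorectal primary-site label to right / left / unknown.

    An unqualified "transverse colon" is ambiguous (the split runs through
    it) and maps to unknown, as does any unrecognized label.
    """
    if not primary_site:
        return "unknown"
    site = primary_site.strip().lower()
    if site in COLORECTAL_RIGHT_SITES:
        return "right"
    if site in COLORECTAL_LEFT_SITES:
        return "left"
    return "unknown"


def map_gastric_region(primary_site: str | None) -> str:
    """Map a gastric primary-site label to its three-way region group."""
    if not primary_site:
        return "unknown"
    site = primary_site.strip().lower()
    for region, synonyms in GASTRIC_REGION_SITES.items():
        if site in synonyms:
            return region
    return "unknown"


def stratify_cohort(
    clinical: Sequence[PatientRecord],
    metrics: Sequence[InstabilityMetrics] | Mapping[str, str],
) -> list[StratumLabel]:
    """Assign MSI-first strata to colorectal and gastric patients.

    ``metrics`` may be the per-patient metrics list or a plain mapping of
    patient id to MSI status. MSI tumors form their own stratum; MSS tumors
    split by anatomical side (colorectal) or region (gastric). Patients of
    other cancer types get scheme "none"; a patient without metrics gets an
    unknown stratum with a warning.
    """
    if isinstance(metrics, Mapping):
        msi_by_pid = dict(metrics)
    else:
        msi_by_pid = {m.patient_id: m.msi_status for m in metrics}
    labels = []
    for rec in clinical:
        status = msi_by_pid.get(rec.patient_id)
        if rec.cancer_type == "CORE":
            if status is None:
                logger.warning("patient %s has no metrics; stratum unknown",
                               rec.patient_id)
                stratum = "MSS_unknown_side"
            elif status == "MSI":
                stratum = "MSI_H"
            else:
                stratum = {"right": "MSS_right", "left": "MSS_left",
                           "unknown": "MSS_unknown_side"}[
                    map_colorectal_side(rec.primary_site)]
            labels.append(StratumLabel(rec.patient_id, "CORE", stratum))
        elif rec.cancer_type == "GAST":
            if status is None:
                logger.warning("patient %s has no metrics; stratum unknown",
                               rec.patient_id)
                stratum = "MSS_unknown"
            elif status == "MSI":
                stratum = "MSI_H"
            else:
                region = map_gastric_region(rec.primary_site)
                stratum = "MSS_unknown" if region == "unknown" else f"MSS_{region}"
            labels.append(StratumLabel(rec.patient_id, "GAST", stratum))
        else:
            labels.append(StratumLabel(rec.patient_id, "none", rec.cancer_type))
    return labels


def strata_to_frame(labels: Sequence[StratumLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": l.patient_id, "scheme": l.scheme, "stratum": l.stratum}
         for l in labels]
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of a full simulated-cohort analysis run."""

    seed: int = 0
    out_dir: str | Path = "gilandscape_report"
    sim_params: CohortSimParams | None = None
    cnv_analysis: bool = True
    reference_counts_path: str | Path | None = None
    q_cutoff: float = 0.1


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Simulate a cohort and produce the full table bundle.

    Writes the simulated inputs, the per-patient instability metrics, gene
    and pathway frequency tables per cancer type, the hyper- vs low-mutation
    MMR/POL comparison, the high- vs low-CIN association tables, the
    MSI/location strata with their comparisons, an optional reference-cohort
    comparison, and a run log. Returns the written paths by table name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    params = config.sim_params or default_sim_params(seed=config.seed)
    outputs: dict[str, Path] = {}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("simulate")
        patients, variants, segments, msi_profiles, truth = generate_cohort(
            params, panel)
        write_clinical(patients, out_dir / "clinical.tsv")
        write_variant_table(variants, out_dir / "variants.tsv")
        write_seg(segments, out_dir / "segments.seg")
        write_msi_profiles(msi_profiles, out_dir / "msi_profiles.tsv")
        _write(truth.to_frame(), out_dir / "truth.tsv")
        for key in ("clinical", "variants", "segments", "msi_profiles", "truth"):
            suffix = "seg" if key == "segments" else "tsv"
            outputs[key] = out_dir / f"{key}.{suffix}"

        name = stage("metrics")
        filtered = filter_variants(variants)
        metrics = compute_cohort_metrics(
            patients, filtered, segments, msi_profiles, panel)
        _write(metrics_to_frame(metrics), out_dir / "metrics.tsv")
        outputs["metrics"] = out_dir / "metrics.tsv"

        name = stage("landscape")
        cnv_calls = (call_gene_cnv(segments, panel.gene_intervals)
                     if config.cnv_analysis else None)
        matrix = build_alteration_matrix(filtered, patients, panel)
        by_type = {p.patient_id: p.cancer_type for p in patients}
        _write(gene_frequencies(matrix, by_type), out_dir / "fig1b_gene_freq.tsv")
        outputs["fig1b_gene_freq"] = out_dir / "fig1b_gene_freq.tsv"
        _write(pathway_alteration_fraction(matrix, panel.pathway_map, by_type),
               out_dir / "fig1c_pathway_fractions.tsv")
        outputs["fig1c_pathway_fractions"] = out_dir / "fig1c_pathway_fractions.tsv"
        if config.cnv_analysis:
            _write(cnv_calls_to_frame(
                [c for c in cnv_calls if c.call != "neutral"]),
                out_dir / "gene_cnv_calls.tsv")
            outputs["gene_cnv_calls"] = out_dir / "gene_cnv_calls.tsv"
        flags, matched = annotate_actionable(
            filtered, default_actionability(), patients)
        act = pd.DataFrame(
            [{"patient_id": p, "actionable": f} for p, f in flags.items()])
        _write(act, out_dir / "actionability.tsv")
        outputs["actionability"] = out_dir / "actionability.tsv"
        _write(matched, out_dir / "actionability_matches.tsv")
        outputs["actionability_matches"] = out_dir / "actionability_matches.tsv"

        name = stage("tmb_comparison")
        tmb_by_pid = {m.patient_id: m.tmb for m in metrics}
        values = [tmb_by_pid[p.patient_id] for p in patients]
        groups = [p.cancer_type for p in patients]
        h, p_kw = kruskal_wallis(values, groups)
        dunn = dunn_posthoc(values, groups)
        dunn.insert(0, "metric", "tmb")
        dunn["kw_H"], dunn["kw_p"] = h, p_kw
        _write(dunn, out_dir / "fig1d_tmb_comparison.tsv")
        outputs["fig1d_tmb_comparison"] = out_dir / "fig1d_tmb_comparison.tsv"

        name = stage("mmr_pol")
        burden = mmr_pol_burden(variants, panel, patients)
        hyper_by_pid = {m.patient_id: m.hypermutated for m in metrics}
        burden["group"] = burden["patient_id"].map(
            lambda p: "hyper_mutated" if hyper_by_pid[p] else "low_mutation")
        _write(burden, out_dir / "fig2c_mmr_pol_burden.tsv")
        outputs["fig2c_mmr_pol_burden"] = out_dir / "fig2c_mmr_pol_burden.tsv"

        name = stage("cin_association")
        cin_group = {m.patient_id: m.cin_group for m in metrics}
        extremes = {p: g for p, g in cin_group.items() if g in ("high", "low")}
        cin_assoc = pairwise_group_test(matrix, extremes,
                                        q_cutoff=config.q_cutoff)
        if config.cnv_analysis:
            cnv_matrix = build_alteration_matrix(
                [], patients, panel, cnv_calls=cnv_calls)
            if cnv_matrix.features:
                cnv_assoc = pairwise_group_test(cnv_matrix, extremes,
                                                q_cutoff=config.q_cutoff)
                cnv_assoc.insert(0, "alteration", "cnv")
                cin_assoc.insert(0, "alteration", "mutation")
                cin_assoc = pd.concat([cin_assoc, cnv_assoc], ignore_index=True)
        _write(cin_assoc, out_dir / "fig3b_cin_assoc.tsv")
        outputs["fig3b_cin_assoc"] = out_dir / "fig3b_cin_assoc.tsv"

        name = stage("stratify")
        strata = stratify_cohort(patients, metrics)
        strata_df = strata_to_frame(strata)
        for scheme, fname in (("CORE", "fig4b_core_strata.tsv"),
                              ("GAST", "fig5b_gast_strata.tsv")):
            sub = strata_df[strata_df["scheme"] == scheme]
            counts = (sub.groupby("stratum").size()
                      .rename("n").reset_index())
            sub = sub.merge(counts, on="stratum")
            _write(sub, out_dir / fname)
            outputs[fname.removesuffix(".tsv")] = out_dir / fname
            stratum_by_pid = dict(zip(sub["patient_id"], sub["stratum"]))
            if sub["stratum"].nunique() >= 2:
                assoc = pairwise_group_test(matrix, stratum_by_pid,
                                            q_cutoff=config.q_cutoff)
                _write(assoc[assoc["tested"]],
                       out_dir / fname.replace("strata", "strata_assoc"))
                outputs[fname.removesuffix(".tsv") + "_assoc"] = (
                    out_dir / fname.replace("strata", "strata_assoc"))

        if config.reference_counts_path is not None:
            name = stage("reference_comparison")
            ref = read_reference_counts(config.reference_counts_path)
            core_ids = [p.patient_id for p in patients if p.cancer_type == "CORE"]
            sub = matrix.values.loc[core_ids]
            ours = {g: (int(sub[g].sum()), len(core_ids))
                    for g in matrix.features if g in ref}
            _write(compare_to_reference(ours, ref, q_cutoff=config.q_cutoff),
                   out_dir / "fig4a_reference_comparison.tsv")
            outputs["fig4a_reference_comparison"] = (
                out_dir / "fig4a_reference_comparison.tsv")

        name = stage("run_log")
        log = {
            "seed": params.seed,
            "version": __version__,
            "n_per_type": params.n_per_type,
            "cnv_analysis": config.cnv_analysis,
            "q_cutoff": config.q_cutoff,
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        outputs["run_log"] = out_dir / "run_log.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return outputs
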