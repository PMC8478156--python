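"""Synthetic GI-cancer cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes — per-cancer-type driver-gene alteration frequencies, a small
microsatellite-unstable (MSI-H) subpopulation with shifted repeat-length
histograms, inflated indels and scarce copy-number changes, a hyper-mutated
subpopulation carrying extra MMR/POL lesions, and per-type distributions of
the chromosomal-instability (CIN) score — together with the ground truth of
every planted label, so that each downstream stage is testable without any
external download.

Construction guarantees (not just expectations): hyper-mutated patients end
strictly above the 20 mut/Mb threshold and everyone else strictly below it;
MSI-H patients have at least the configured fraction of loci shifted by at
least the configured magnitude; generated segments realize the target CIN
score exactly up to integer base-pair rounding.

All randomness is derived from one seed through independent per-patient
substreams keyed by (family, cancer type, patient index), so enlarging one
cancer type never perturbs the draws of existing patients.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .core_model import (
    CNSegment,
    GenePanel,
    MSILocusProfile,
    PatientRecord,
    VariantCall,
    default_panel,
)

CANCER_ORDER = ("CORE", "GAST", "PAAD", "GABI", "GIST")
_ID_PREFIX = {"CORE": "CO", "GAST": "GA", "PAAD": "PA", "GABI": "GB", "GIST": "GI"}

#: simplified 22-autosome covered-territory model (bp)
DEFAULT_CHROM_LENGTHS = {
    f"chr{i}": 250_000_000 - (i - 1) * 9_000_000 for i in range(1, 23)
}

# per-cancer-type driver alteration probabilities (calibration defaults)
DEFAULT_GENE_FREQ: dict[str, dict[str, float]] = {
    "CORE": {
        "TP53": 0.82, "APC": 0.60, "KRAS": 0.50, "PIK3CA": 0.20, "RNF43": 0.14,
        "SMAD4": 0.12, "GNAS": 0.11, "FBXW7": 0.10, "ARID1A": 0.10, "POLE": 0.09,
        "NF1": 0.09, "AMER1": 0.09, "KMT2B": 0.08, "SMARCA4": 0.07, "AXIN2": 0.06,
        "CTNNB1": 0.05, "ERCC2": 0.05, "BRAF": 0.05, "CHD4": 0.04, "LZTR1": 0.04,
        "SMAD2": 0.01,
    },
    "GAST": {
        "TP53": 0.70, "ARID1A": 0.15, "KRAS": 0.11, "APC": 0.10, "CDH1": 0.10,
        "PIK3CA": 0.10, "ERBB2": 0.08, "RNF43": 0.06, "CCNE1": 0.05,
        "PBRM1": 0.03, "ERBB3": 0.03,
    },
    "PAAD": {"KRAS": 0.74, "TP53": 0.59, "SMAD4": 0.25, "CDKN2A": 0.20,
             "APC": 0.04},
    "GABI": {"TP53": 0.64, "KRAS": 0.21, "ERBB2": 0.10, "ARID1A": 0.10,
             "APC": 0.07},
    "GIST": {"KIT": 0.73, "PDGFRA": 0.10, "TP53": 0.09, "NF1": 0.05},
}

DEFAULT_N_PER_TYPE = {"CORE": 207, "GAST": 144, "PAAD": 27, "GABI": 14, "GIST": 22}
DEFAULT_MSI_H_FRACTION = {"CORE": 11 / 207, "GAST": 5 / 124, "PAAD": 0.0,
                          "GABI": 0.0, "GIST": 0.0}
DEFAULT_HYPER_FRACTION = {"CORE": 0.09, "GAST": 0.03, "PAAD": 0.0, "GABI": 0.0,
                          "GIST": 0.0}
DEFAULT_TMB_MEDIAN = {"CORE": 6.0, "GAST": 5.0, "PAAD": 4.0, "GABI": 4.0,
                      "GIST": 2.5}
DEFAULT_CIN_MEDIAN = {"CORE": 0.31, "GAST": 0.27, "PAAD": 0.11, "GABI": 0.18,
                      "GIST": 0.40}

# anatomical site sampling: (label or None, probability)
_SITE_MODEL: dict[str, list[tuple[str | None, float]]] = {
    "CORE": [
        ("rectum", 0.29), ("sigmoid colon", 0.22), ("descending colon", 0.14),
        ("transverse colon distal", 0.07),          # left-sided: 0.72
        ("ascending colon", 0.12), ("cecum", 0.07),
        ("transverse colon proximal", 0.04),        # right-sided: 0.23
        (None, 0.05),
    ],
    "GAST": [
        ("cardia", 0.20), ("fundus", 0.22), ("body", 0.30),
        ("antrum", 0.15), ("pylorus", 0.05), ("duodenum", 0.03), (None, 0.05),
    ],
    "PAAD": [("head of pancreas", 0.6), ("body of pancreas", 0.25),
             ("tail of pancreas", 0.15)],
    "GABI": [("gallbladder", 0.6), ("common bile duct", 0.4)],
    "GIST": [("stomach", 0.6), ("small intestine", 0.4)],
}

_HOTSPOTS = {
    "KRAS": ["p.G12D", "p.G12V", "p.G13D", "p.Q61H"],
    "PIK3CA": ["p.E542K", "p.E545K", "p.H1047R"],
    "BRAF": ["p.V600E"],
}


@dataclass
class MSINoiseParams:
    """Stutter / shift model for microsatellite read-length histograms."""

    stutter_prob: float = 0.12       # per-read chance of any PCR contraction
    stutter_decay: float = 0.75      # geometric stop prob for extra contraction
    mean_depth: float = 400.0        # Poisson mean reads per locus
    shifted_locus_fraction: float = 0.6   # loci shifted in an MSI-H tumor
    min_shift_bp: int = 3            # minimum somatic shortening
    extra_shift_poisson: float = 1.0  # Poisson extra on top of the minimum
    normal_allele_fraction: float = 0.3   # unshifted reads at a shifted locus


@dataclass
class CohortSimParams:
    """Study conditions for the simulated cohort."""

    n_per_type: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_TYPE))
    gene_freq: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(g) for t, g in DEFAULT_GENE_FREQ.items()})
    msi_h_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MSI_H_FRACTION))
    hyper_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYPER_FRACTION))
    tmb_median: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TMB_MEDIAN))
    tmb_sigma: float = 0.65
    tmb_nonhyper_cap: float = 18.0   # keeps non-hyper tumors clear of 20 mut/Mb
    tmb_hyper_min: float = 25.0      # keeps hyper tumors clear of 20 mut/Mb
    cin_median: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CIN_MEDIAN))
    msi_h_cin_median: float = 0.10   # scarce CNVs in MSI-H tumors
    # planted MMR/POL lesion rate in low-mutation tumors; chosen so that the
    # overall carrier prevalence (planted lesions + POLE driver frequency +
    # background mutations falling in the nine MMR/POL genes) is ~30%
    mmr_lesion_prob_low: float = 0.15
    msi_noise: MSINoiseParams = field(default_factory=MSINoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, table in (("msi_h_fraction", self.msi_h_fraction),
                            ("hyper_fraction", self.hyper_fraction)):
            for t, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{t}] = {p} outside [0, 1]")
        for t, n in self.n_per_type.items():
            if n < 0:
                raise ValueError(f"n_per_type[{t}] must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    cancer_type: str
    msi_h: bool
    hypermutated: bool
    cin_target: float
    tmb_target: float
    mmr_pol_lesions: tuple[str, ...]


@dataclass
class CohortTruth:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"patient_id": r.patient_id, "cancer_type": r.cancer_type,
                 "msi_h": r.msi_h, "hypermutated": r.hypermutated,
                 "cin_target": r.cin_target, "tmb_target": r.tmb_target,
                 "mmr_pol_lesions": ",".join(r.mmr_pol_lesions)}
                for r in self.records.values()
            ]
        )


def default_sim_params(seed: int = 0) -> CohortSimParams:
    return CohortSimParams(seed=seed)


# family indices for the independent generator streams
_FAM_CLINICAL, _FAM_VARIANTS, _FAM_SEGMENTS, _FAM_MSI = range(4)


def _rng(seed: int, family: int, type_idx: int, patient_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(family, type_idx, patient_idx))
    )


@lru_cache(maxsize=None)
def _beta_params_for_median(m: float, concentration: float = 10.0) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration whose median equals ``m``."""
    m = float(np.clip(m, 0.005, 0.995))
    lo, hi = 0.02, concentration - 0.02

    def err(a: float) -> float:
        return sps.beta.median(a, concentration - a) - m

    a = optimize.brentq(err, lo, hi, xtol=1e-6)
    return a, concentration - a


# ---------------------------------------------------------------------------
# copy-number segments


def generate_segments(
    cin_target: float,
    patient_id: str = "S1",
    chrom_lengths: Mapping[str, int] | None = None,
    seed: int | np.random.Generator = 0,
    breaks_per_chrom: int = 3,
) -> list[CNSegment]:
    """Tile the covered territory with segments realizing a CIN target.

    The returned segments cover every chromosome of ``chrom_lengths``
    completely, and the length-weighted fraction with \\|log2\\| > 0.2 equals
    ``cin_target`` up to integer base-pair rounding (well within +/-0.02).
    """
    if not 0.0 <= cin_target <= 1.0:
        raise ValueError(f"cin_target {cin_target} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)

    pieces: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        cuts = np.sort(rng.integers(1, length, size=breaks_per_chrom))
        bounds = np.unique(np.concatenate([[0], cuts, [length]]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            pieces.append((chrom, int(s), int(e)))

    total = sum(e - s for _, s, e in pieces)
    want = int(round(cin_target * total))
    order = rng.permutation(len(pieces))

    segments: list[CNSegment] = []
    remaining = want

    def aberrant_log2() -> float:
        mag = min(0.25 + rng.exponential(0.25), 1.5)
        return mag if rng.random() < 0.5 else -mag

    def neutral_log2() -> float:
        return float(rng.uniform(-0.12, 0.12))

    for i in order:
        chrom, s, e = pieces[i]
        length = e - s
        if remaining >= length:
            segments.append(CNSegment(patient_id, chrom, s, e, aberrant_log2()))
            remaining -= length
        elif remaining > 0:
            mid = s + remaining
            segments.append(CNSegment(patient_id, chrom, s, mid, aberrant_log2()))
            segments.append(CNSegment(patient_id, chrom, mid, e, neutral_log2()))
            remaining = 0
        else:
            segments.append(CNSegment(patient_id, chrom, s, e, neutral_log2()))
    def _chrom_key(c: str) -> tuple[int, object]:
        t = c.removeprefix("chr")
        return (0, int(t)) if t.isdigit() else (1, t)

    segments.sort(key=lambda g: (_chrom_key(g.chrom), g.start))
    return segments


# ---------------------------------------------------------------------------
# microsatellite locus profiles


def _stutter_distribution(ref_len: int, noise: MSINoiseParams,
                          max_contraction: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Lengths and probabilities of the PCR-stutter contraction ladder."""
    ks = np.arange(max_contraction + 1)
    probs = np.empty_like(ks, dtype=float)
    probs[0] = 1.0 - noise.stutter_prob
    geom = noise.stutter_decay * (1.0 - noise.stutter_decay) ** (ks[1:] - 1)
    probs[1:] = noise.stutter_prob * geom / geom.sum()
    lengths = np.maximum(ref_len - ks, 1)
    return lengths, probs


def generate_msi_locus_profiles(
    truth_status: Mapping[str, bool],
    panel: GenePanel,
    noise: MSINoiseParams | None = None,
    seed: int = 0,
    _rngs: Mapping[str, np.random.Generator] | None = None,
) -> list[MSILocusProfile]:
    """Per-patient repeat-length histograms at the panel's MSI loci.

    Stable patients get histograms centered at the reference length with a
    geometric stutter-contraction tail. For MSI-H patients a configured
    fraction of loci (guaranteed by construction, topped up if the Bernoulli
    draws fall short) is shifted shorter by at least ``min_shift_bp``, with
    a residual unshifted-allele read fraction. A zero mean depth yields
    empty histograms (all loci unqualified downstream).
    """
    noise = noise or MSINoiseParams()
    profiles: list[MSILocusProfile] = []
    n_loci = len(panel.msi_loci)
    min_shifted = int(np.ceil(noise.shifted_locus_fraction * n_loci))
    for idx, (pid, is_msi_h) in enumerate(truth_status.items()):
        rng = (_rngs[pid] if _rngs is not None
               else np.random.default_rng(np.random.SeedSequence(
                   entropy=seed, spawn_key=(_FAM_MSI, 0, idx))))
        if is_msi_h and n_loci:
            shifted = rng.random(n_loci) < noise.shifted_locus_fraction
            shortfall = min_shifted - int(shifted.sum())
            if shortfall > 0:  # construction guarantee on the shifted fraction
                candidates = np.flatnonzero(~shifted)
                shifted[rng.choice(candidates, size=shortfall, replace=False)] = True
        else:
            shifted = np.zeros(n_loci, dtype=bool)
        for li, locus in enumerate(panel.msi_loci):
            depth = int(rng.poisson(noise.mean_depth)) if noise.mean_depth > 0 else 0
            if depth == 0:
                profiles.append(MSILocusProfile(
                    pid, locus.locus_id, locus.repeat_unit,
                    locus.reference_repeat_len, {}))
                continue
            ref = locus.reference_repeat_len
            lengths, probs = _stutter_distribution(ref, noise)
            if shifted[li]:
                shift = noise.min_shift_bp + int(rng.poisson(noise.extra_shift_poisson))
                s_lengths, s_probs = _stutter_distribution(max(ref - shift, 1), noise)
                lengths = np.concatenate([lengths, s_lengths])
                probs = np.concatenate([
                    probs * noise.normal_allele_fraction,
                    s_probs * (1.0 - noise.normal_allele_fraction),
                ])
            counts = rng.multinomial(depth, probs / probs.sum())
            hist: dict[int, int] = {}
            for l, c in zip(lengths, counts):
                if c > 0:
                    hist[int(l)] = hist.get(int(l), 0) + int(c)
            profiles.append(MSILocusProfile(
                pid, locus.locus_id, locus.repeat_unit, ref, hist))
    return profiles


# ---------------------------------------------------------------------------
# variants


def _random_protein_change(rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return (f"p.{aas[rng.integers(len(aas))]}{int(rng.integers(20, 900))}"
            f"{aas[rng.integers(len(aas))]}")


def _make_variant(
    rng: np.random.Generator,
    pid: str,
    gene: str,
    variant_class: str,
    panel: GenePanel,
    origin: str = "somatic",
    protein_change: str | None = None,
    passing: bool = True,
) -> VariantCall:
    chrom, gstart, gend = panel.gene_intervals.get(
        gene, ("chr1", 1_000_000, 1_100_000))
    pos = int(rng.integers(gstart, gend))
    if origin == "germline":
        vaf = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
    else:
        vaf = float(np.clip(rng.beta(2.0, 5.0), 0.02, 0.95))
    if passing:
        fwd = max(3, int(rng.poisson(max(vaf, 0.02) * 250)))
        rev = max(3, int(rng.poisson(max(vaf, 0.02) * 250)))
    else:  # deliberately below the retention filter
        if rng.random() < 0.5:
            vaf = float(rng.uniform(0.001, 0.009))
            fwd, rev = max(3, int(rng.poisson(4))), max(3, int(rng.poisson(4)))
        else:
            fwd, rev = int(rng.integers(0, 3)), int(rng.integers(0, 3))
    if protein_change is None and variant_class in (
            "missense", "nonsense", "stop_gain"):
        protein_change = _random_protein_change(rng)
    return VariantCall(
        patient_id=pid, gene=gene, variant_class=variant_class, origin=origin,
        chrom=chrom, pos=pos, protein_change=protein_change, vaf=vaf,
        alt_reads_fwd=fwd, alt_reads_rev=rev, in_target=True,
    )


def _driver_class_and_protein(
    rng: np.random.Generator, gene: str, cancer_type: str
) -> tuple[str, str | None]:
    if gene == "KIT" and cancer_type == "GIST":
        # exon-11 in-frame deletions dominate
        return "inframe_indel", f"p.K{int(rng.integers(550, 560))}del"
    if gene in _HOTSPOTS and rng.random() < 0.7:
        return "missense", _HOTSPOTS[gene][rng.integers(len(_HOTSPOTS[gene]))]
    r = rng.random()
    if r < 0.70:
        return "missense", None
    if r < 0.80:
        return "nonsense", None
    if r < 0.90:
        return "frameshift_indel", None
    if r < 0.95:
        return "splice_site", None
    return "inframe_indel", None


def _background_class(rng: np.random.Generator, msi_h: bool) -> str:
    indel_p = 0.45 if msi_h else 0.10  # MSI-H tumors have inflated indels
    r = rng.random()
    if r < indel_p:
        return "frameshift_indel"
    if r < indel_p + 0.05:
        return "inframe_indel"
    return "missense"


def _patient_variants(
    rng: np.random.Generator,
    pid: str,
    cancer_type: str,
    truth: TruthRecord,
    params: CohortSimParams,
    panel: GenePanel,
) -> list[VariantCall]:
    variants: list[VariantCall] = []
    freq = params.gene_freq.get(cancer_type, {})
    for gene in sorted(freq):
        if rng.random() < freq[gene]:
            vclass, pc = _driver_class_and_protein(rng, gene, cancer_type)
            variants.append(_make_variant(rng, pid, gene, vclass, panel,
                                          protein_change=pc))
    for lesion_gene in truth.mmr_pol_lesions:
        origin = "germline" if rng.random() < 0.3 else "somatic"
        vclass = "frameshift_indel" if rng.random() < 0.5 else "missense"
        variants.append(_make_variant(rng, pid, lesion_gene, vclass, panel,
                                      origin=origin))
    n_target = int(round(truth.tmb_target * panel.target_size_mb))
    qualifying = sum(
        1 for v in variants
        if v.origin == "somatic" and v.variant_class != "fusion"
    )
    panel_genes = panel.genes
    for _ in range(max(0, n_target - qualifying)):
        gene = panel_genes[rng.integers(len(panel_genes))]
        variants.append(_make_variant(
            rng, pid, gene, _background_class(rng, truth.msi_h), panel))
    # sprinkle sub-threshold artifacts that the retention filter removes
    for _ in range(rng.poisson(2.0)):
        gene = panel_genes[rng.integers(len(panel_genes))]
        variants.append(_make_variant(rng, pid, gene, "missense", panel,
                                      passing=False))
    return variants


# ---------------------------------------------------------------------------
# the cohort


def _sample_site(rng: np.random.Generator, cancer_type: str) -> str | None:
    labels, probs = zip(*_SITE_MODEL[cancer_type])
    return labels[rng.choice(len(labels), p=np.asarray(probs) / sum(probs))]


def generate_cohort(
    params: CohortSimParams | None = None,
    panel: GenePanel | None = None,
) -> tuple[list[PatientRecord], list[VariantCall], list[CNSegment],
           list[MSILocusProfile], CohortTruth]:
    """Generate a full synthetic cohort plus its planted ground truth.

    Deterministic given ``params.seed``; a zero-size cohort yields empty
    outputs.
    """
    params = params or default_sim_params()
    panel = panel or default_panel()
    mmr_pol = sorted(panel.mmr_genes) + sorted(panel.pol_genes)
    mmr_only = sorted(panel.mmr_genes)

    patients: list[PatientRecord] = []
    variants: list[VariantCall] = []
    segments: list[CNSegment] = []
    msi_profiles: list[MSILocusProfile] = []
    truth = CohortTruth()

    for type_idx, cancer_type in enumerate(CANCER_ORDER):
        n = params.n_per_type.get(cancer_type, 0)
        for i in range(n):
            pid = f"{_ID_PREFIX[cancer_type]}_{i + 1:03d}"
            rng_c = _rng(params.seed, _FAM_CLINICAL, type_idx, i)
            rng_v = _rng(params.seed, _FAM_VARIANTS, type_idx, i)
            rng_s = _rng(params.seed, _FAM_SEGMENTS, type_idx, i)
            rng_m = _rng(params.seed, _FAM_MSI, type_idx, i)

            is_msi_h = rng_c.random() < params.msi_h_fraction.get(cancer_type, 0.0)
            is_hyper = rng_c.random() < params.hyper_fraction.get(cancer_type, 0.0)

            if is_hyper:
                tmb = params.tmb_hyper_min + float(
                    rng_c.lognormal(np.log(10.0), 0.9))
                tmb = min(tmb, 185.0)
                n_lesions = (1 + int(rng_c.poisson(1.0))
                             if rng_c.random() < 0.95 else 0)
                lesions = tuple(
                    mmr_pol[j] for j in rng_c.choice(
                        len(mmr_pol), size=min(n_lesions, len(mmr_pol)),
                        replace=False)
                )
            else:
                tmb = float(np.clip(
                    rng_c.lognormal(np.log(params.tmb_median[cancer_type]),
                                    params.tmb_sigma),
                    0.9, params.tmb_nonhyper_cap))
                lesions = ()
                if rng_c.random() < params.mmr_lesion_prob_low:
                    lesions = (mmr_pol[rng_c.integers(len(mmr_pol))],)
            if is_msi_h and not any(g in panel.mmr_genes for g in lesions):
                if rng_c.random() < 0.95:  # MSI-H tumors carry an MMR lesion
                    lesions = lesions + (
                        mmr_only[rng_c.integers(len(mmr_only))],)

            if is_msi_h:
                a, b = _beta_params_for_median(params.msi_h_cin_median)
            else:
                a, b = _beta_params_for_median(params.cin_median[cancer_type])
            cin_target = float(np.clip(rng_c.beta(a, b), 0.0, 1.0))

            rec = TruthRecord(
                patient_id=pid, cancer_type=cancer_type, msi_h=is_msi_h,
                hypermutated=is_hyper, cin_target=cin_target, tmb_target=tmb,
                mmr_pol_lesions=lesions,
            )
            truth.records[pid] = rec

            age = float(np.clip(rng_c.normal(62.0, 10.0), 25.0, 90.0))
            stage = rng_c.choice(["IV", "III", "II", "I"],
                                 p=[0.80, 0.12, 0.05, 0.03])
            sex = "M" if rng_c.random() < 0.6 else "F"
            patients.append(PatientRecord(
                patient_id=pid, cancer_type=cancer_type,
                primary_site=_sample_site(rng_c, cancer_type),
                stage=str(stage), age=round(age, 1), sex=sex,
            ))

            variants.extend(
                _patient_variants(rng_v, pid, cancer_type, rec, params, panel))
            segments.extend(generate_segments(
                cin_target, patient_id=pid, seed=rng_s))
            msi_profiles.extend(generate_msi_locus_profiles(
                {pid: is_msi_h}, panel, params.msi_noise, _rngs={pid: rng_m}))

    return patients, variants, segments, msi_profiles, truth
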