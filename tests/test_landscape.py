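"""Alteration matrices, frequencies, CNV calls, actionability, MMR/POL."""
import numpy as np
import pytest
from scipy import stats as sps

from gilandscape.core_model import (
    CNSegment,
    PatientRecord,
    VariantCall,
    default_actionability,
)
from gilandscape.landscape import (
    annotate_actionable,
    build_alteration_matrix,
    call_gene_cnv,
    gene_frequencies,
    mmr_pol_burden,
    pathway_alteration_fraction,
    percent,
)


def _var(pid="P1", gene="TP53", vclass="missense", origin="somatic",
         protein=None):
    return VariantCall(patient_id=pid, gene=gene, variant_class=vclass,
                       origin=origin, chrom="chr1", pos=10, vaf=0.2,
                       alt_reads_fwd=20, alt_reads_rev=20,
                       protein_change=protein)


def _patients(n, cancer_type="CORE"):
    return [PatientRecord(patient_id=f"P{i}", cancer_type=cancer_type)
            for i in range(n)]


class TestPercent:
    @pytest.mark.parametrize("n,d,expected", [
        (296, 414, 71), (141, 414, 34), (137, 414, 33),
        (117, 388, 30), (149, 207, 72), (0, 50, 0), (1, 200, 1),
    ])
    def test_integer_display_rounding(self, n, d, expected):
        assert percent(n, d) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent(1, 8) == 13  # 12.5 -> 13


class TestAlterationMatrix:
    def test_binary_despite_multiple_hits(self, panel):
        patients = _patients(2)
        variants = [_var(), _var(protein="p.R175H")]
        m = build_alteration_matrix(variants, patients, panel)
        assert bool(m.values.at["P0", "TP53"]) is False
        assert bool(m.values.at["P1", "TP53"]) is True
        assert m.values["TP53"].sum() == 1
        assert m.provenance.at["P1", "TP53"] == "mutation"

    def test_germline_only_excluded(self, panel):
        patients = _patients(1, "CORE")
        m = build_alteration_matrix([_var(pid="P0", gene="MSH2",
                                          origin="germline")],
                                    patients, panel)
        assert "MSH2" not in m.features or not m.values.at["P0", "MSH2"]

    def test_all_patients_present_even_if_zero(self, panel):
        m = build_alteration_matrix([_var(pid="P0")], _patients(3), panel)
        assert m.patients == ["P0", "P1", "P2"]

    def test_fusion_toggle(self, panel):
        variants = [_var(pid="P0", gene="ALK", vclass="fusion")]
        with_f = build_alteration_matrix(variants, _patients(1), panel)
        without = build_alteration_matrix(variants, _patients(1), panel,
                                          fusions_included=False)
        assert with_f.values.at["P0", "ALK"]
        assert "ALK" not in without.features or not without.values.at["P0", "ALK"]

    def test_column_sums_match_frequency_counts(self, panel):
        rng = np.random.default_rng(5)
        patients = _patients(20)
        variants = [_var(pid=f"P{i}", gene=g)
                    for i in range(20) for g in ("TP53", "APC", "KRAS")
                    if rng.random() < 0.4]
        m = build_alteration_matrix(variants, patients, panel)
        freq = gene_frequencies(m)
        for _, row in freq.iterrows():
            assert row["n_altered"] == int(m.values[row["gene"]].sum())

    def test_synthetic_core_tp53_frequency(self, full_cohort_filtered, panel):
        patients, filtered, *_ = full_cohort_filtered
        core = [p for p in patients if p.cancer_type == "CORE"]
        m = build_alteration_matrix(
            [v for v in filtered
             if v.patient_id in {p.patient_id for p in core}], core, panel)
        n = int(m.values["TP53"].sum())
        lo, hi = sps.binom.ppf([0.025, 0.975], len(core), 0.82)
        assert lo <= n <= hi


class TestPathwayFractions:
    def test_counted_once_per_pathway(self, panel):
        m = build_alteration_matrix([_var(pid="P0", gene="APC")],
                                    _patients(4), panel)
        frac = pathway_alteration_fraction(m, panel.pathway_map)
        wnt = frac[frac.pathway == "Wnt"].iloc[0]
        assert wnt["n_altered"] == 1 and wnt["fraction"] == 0.25

    def test_bounds_by_member_genes(self, full_cohort_filtered, panel):
        patients, filtered, *_ = full_cohort_filtered
        core = [p for p in patients if p.cancer_type == "CORE"]
        ids = {p.patient_id for p in core}
        m = build_alteration_matrix([v for v in filtered if v.patient_id in ids],
                                    core, panel)
        freq = gene_frequencies(m).set_index("gene")["frequency"]
        frac = pathway_alteration_fraction(m, panel.pathway_map)
        for _, row in frac.iterrows():
            members = [g for g in panel.pathway_map[row["pathway"]]
                       if g in freq.index]
            if not members or row["fraction"] is None:
                continue
            assert row["fraction"] >= max(freq[g] for g in members) - 1e-12
            assert row["fraction"] <= sum(freq[g] for g in members) + 1e-12

    def test_core_wnt_fraction_at_least_apc(self, full_cohort_filtered, panel):
        patients, filtered, *_ = full_cohort_filtered
        core = [p for p in patients if p.cancer_type == "CORE"]
        ids = {p.patient_id for p in core}
        m = build_alteration_matrix([v for v in filtered if v.patient_id in ids],
                                    core, panel)
        freq = gene_frequencies(m).set_index("gene")["frequency"]
        frac = pathway_alteration_fraction(m, panel.pathway_map)
        wnt = frac[frac.pathway == "Wnt"]["fraction"].iloc[0]
        assert wnt >= freq["APC"]


class TestGeneCNV:
    def test_gene_inside_gain_segment(self):
        segs = [CNSegment("P1", "chr1", 0, 10**7, 0.6)]
        calls = call_gene_cnv(segs, {"G1": ("chr1", 10**6, 2 * 10**6)})
        assert calls[0].call == "gain"

    def test_weighted_mean_below_cutoff_is_neutral(self):
        # 30% of the gene at +0.6 and 70% at 0.0 -> mean 0.18 -> neutral
        segs = [CNSegment("P1", "chr1", 0, 300, 0.6),
                CNSegment("P1", "chr1", 300, 1000, 0.0)]
        calls = call_gene_cnv(segs, {"G1": ("chr1", 0, 1000)})
        assert calls[0].mean_log2 == pytest.approx(0.18)
        assert calls[0].call == "neutral"

    def test_low_coverage_is_neutral(self):
        segs = [CNSegment("P1", "chr1", 0, 100, -0.9)]
        calls = call_gene_cnv(segs, {"G1": ("chr1", 0, 1000)})
        assert calls[0].call == "neutral" and calls[0].covered_fraction == 0.1

    def test_adjacent_genes_in_one_deletion_concur(self, panel):
        wrn, nat1 = panel.gene_intervals["WRN"], panel.gene_intervals["NAT1"]
        assert wrn[0] == nat1[0] == "chr8"
        segs = [CNSegment("P1", "chr8", 25_000_000, 35_000_000, -0.8)]
        calls = {c.gene: c.call for c in call_gene_cnv(
            segs, {"WRN": wrn, "NAT1": nat1})}
        assert calls == {"WRN": "loss", "NAT1": "loss"}

    def test_split_invariance(self):
        segs = [CNSegment("P1", "chr1", 0, 1000, 0.5)]
        split = [CNSegment("P1", "chr1", 0, 400, 0.5),
                 CNSegment("P1", "chr1", 400, 1000, 0.5)]
        iv = {"G1": ("chr1", 100, 900)}
        c1, c2 = call_gene_cnv(segs, iv)[0], call_gene_cnv(split, iv)[0]
        assert c1.call == c2.call and c1.mean_log2 == pytest.approx(c2.mean_log2)

    def test_absent_chromosome_neutral(self):
        segs = [CNSegment("P1", "chr1", 0, 1000, 0.5)]
        calls = call_gene_cnv(segs, {"G1": ("chr2", 0, 100)})
        assert calls[0].call == "neutral"


class TestActionability:
    def test_hotspot_matches(self):
        rules = default_actionability()
        flags, matched = annotate_actionable(
            [_var(gene="KRAS", protein="p.G12D"),
             _var(pid="P2", gene="BRAF", protein="p.V600E"),
             _var(pid="P3", gene="TP53", protein="p.R175H")],
            rules)
        assert flags == {"P1": True, "P2": True, "P3": False}
        assert set(matched["gene"]) == {"KRAS", "BRAF"}

    def test_class_rule_and_whitelist(self):
        rules = default_actionability()
        flags, _ = annotate_actionable(
            [_var(gene="KIT", vclass="inframe_indel"),
             _var(pid="P2", gene="KIT", vclass="fusion")],  # class not eligible
            rules)
        assert flags == {"P1": True, "P2": False}

    def test_germline_not_actionable(self):
        rules = default_actionability()
        flags, _ = annotate_actionable(
            [_var(gene="KRAS", protein="p.G12D", origin="germline")], rules)
        assert flags == {"P1": False}


class TestMMRPolBurden:
    def test_somatic_plus_germline_count(self, panel):
        variants = [_var(gene="MSH6"),
                    _var(gene="PMS2", origin="germline"),
                    _var(gene="TP53")]
        df = mmr_pol_burden(variants, panel).set_index("patient_id")
        assert df.loc["P1", "n_mmr_pol"] == 2
        assert df.loc["P1", "n_somatic"] == 1
        assert df.loc["P1", "n_germline"] == 1
        assert bool(df.loc["P1", "has_any"])

    def test_zero_burden(self, panel):
        df = mmr_pol_burden([_var(gene="TP53")], panel,
                            _patients(2)).set_index("patient_id")
        assert df.loc["P0", "n_mmr_pol"] == 0
        assert not bool(df.loc["P0", "has_any"])

    def test_hyper_group_median_exceeds_low(self, full_cohort, panel):
        patients, variants, _, _, truth = full_cohort
        df = mmr_pol_burden(variants, panel, patients).set_index("patient_id")
        hyper = [df.loc[r.patient_id, "n_mmr_pol"]
                 for r in truth.records.values() if r.hypermutated]
        low = [df.loc[r.patient_id, "n_mmr_pol"]
               for r in truth.records.values() if not r.hypermutated]
        assert np.median(hyper) > np.median(low)
        u, p = sps.mannwhitneyu(hyper, low, alternative="greater")
        assert p < 1e-6
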