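"""TMB, CIN scoring/grouping and MSI calling."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gilandscape.core_model import CNSegment, MSILocusProfile, VariantCall
from gilandscape.instability import (
    BaselineLocus,
    MSIBaseline,
    build_msi_baseline,
    call_msi,
    classify_cin_groups,
    classify_hypermutated,
    compute_cin_score,
    compute_tmb,
    score_locus_instability,
)


def _somatic(n, vclass="missense", in_target=True):
    return [
        VariantCall(patient_id="P1", gene="TP53", variant_class=vclass,
                    origin="somatic", chrom="chr1", pos=i, vaf=0.1,
                    alt_reads_fwd=10, alt_reads_rev=10, in_target=in_target)
        for i in range(n)
    ]


def _profile(hist, locus="L01", pid="P1", ref=16):
    return MSILocusProfile(patient_id=pid, locus_id=locus, repeat_unit="A",
                           reference_repeat_len=ref, histogram=hist)


def _baseline(loci, support_lengths=(16,)):
    return MSIBaseline(
        loci={l: BaselineLocus(frequencies={s: 1 / len(support_lengths)
                                            for s in support_lengths},
                               support=frozenset(support_lengths), n_samples=10)
              for l in loci},
        n_pool_samples=10,
    )


class TestTMB:
    def test_zero_variants(self, panel):
        assert compute_tmb([], panel) == 0.0

    def test_per_megabase_scaling(self, panel):
        assert compute_tmb(_somatic(30), panel) == pytest.approx(25.0)
        assert compute_tmb(_somatic(54), panel) == pytest.approx(45.0)

    def test_exclusions(self, panel):
        variants = _somatic(12) + _somatic(5, vclass="fusion")
        variants += _somatic(3, in_target=False)
        germ = [VariantCall(patient_id="P1", gene="MSH2",
                            variant_class="missense", origin="germline",
                            chrom="chr1", pos=1, vaf=0.5, alt_reads_fwd=50,
                            alt_reads_rev=50)]
        assert compute_tmb(variants + germ, panel) == pytest.approx(10.0)

    def test_linear_in_count(self, panel):
        t10, t20 = compute_tmb(_somatic(10), panel), compute_tmb(_somatic(20), panel)
        assert t20 == pytest.approx(2 * t10)

    def test_bad_target_size(self, panel):
        import dataclasses
        with pytest.raises(ValueError):
            bad = dataclasses.replace(panel)
            bad.target_size_mb = 0.0
            compute_tmb(_somatic(1), bad)


class TestHypermutation:
    @pytest.mark.parametrize("tmb,expected",
                             [(45.0, True), (20.0, False), (20.01, True),
                              (0.0, False)])
    def test_strict_threshold(self, tmb, expected):
        assert classify_hypermutated(tmb) is expected


class TestCINScore:
    def test_all_neutral(self):
        segs = [CNSegment("P", "chr1", 0, 100, 0.0)]
        assert compute_cin_score(segs) == 0.0

    def test_whole_genome_aberrant(self):
        segs = [CNSegment("P", "chr1", 0, 10**8, 0.5)]
        assert compute_cin_score(segs) == 1.0

    def test_length_weighted_hand_case(self):
        mb = 10**6
        segs = [
            CNSegment("P", "chr1", 0, 10 * mb, 0.25),
            CNSegment("P", "chr1", 10 * mb, 40 * mb, -0.1),
            CNSegment("P", "chr1", 40 * mb, 100 * mb, -0.3),
        ]
        assert compute_cin_score(segs) == pytest.approx(0.7)

    def test_empty_is_not_evaluable(self):
        assert compute_cin_score([]) is None

    def test_boundary_log2_is_neutral(self):
        segs = [CNSegment("P", "chr1", 0, 100, 0.2),
                CNSegment("P", "chr1", 100, 200, -0.2)]
        assert compute_cin_score(segs) == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_split_invariance(self, seed):
        rng = np.random.default_rng(seed)
        segs = []
        pos = 0
        for _ in range(rng.integers(1, 12)):
            length = int(rng.integers(2, 10**6))
            segs.append(CNSegment("P", "chr1", pos, pos + length,
                                  float(rng.normal(0, 0.4))))
            pos += length
        score = compute_cin_score(segs)
        i = int(rng.integers(len(segs)))
        s = segs[i]
        mid = int(rng.integers(s.start + 1, s.end))
        split = (segs[:i]
                 + [CNSegment("P", "chr1", s.start, mid, s.log2_ratio),
                    CNSegment("P", "chr1", mid, s.end, s.log2_ratio)]
                 + segs[i + 1:])
        assert compute_cin_score(split) == pytest.approx(score)


class TestCINGroups:
    def test_four_scores(self):
        groups = classify_cin_groups({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4})
        assert groups == {"a": "low", "b": "mid", "c": "mid", "d": "high"}

    def test_all_identical_all_mid(self):
        groups = classify_cin_groups({f"p{i}": 0.3 for i in range(8)})
        assert set(groups.values()) == {"mid"}

    def test_hundred_distinct_quartiles(self):
        rng = np.random.default_rng(0)
        scores = {f"p{i}": s for i, s in
                  enumerate(rng.permutation(np.linspace(0.001, 0.999, 100)))}
        groups = classify_cin_groups(scores)
        counts = {g: sum(1 for v in groups.values() if v == g)
                  for g in ("high", "mid", "low")}
        assert counts == {"high": 25, "mid": 50, "low": 25}
        # the extreme groups hold the extreme values
        ordered = sorted(scores, key=scores.get)
        assert all(groups[p] == "low" for p in ordered[:25])
        assert all(groups[p] == "high" for p in ordered[-25:])

    def test_too_few_scores(self):
        groups = classify_cin_groups({"a": 0.1, "b": None, "c": 0.2})
        assert set(groups.values()) == {"not_evaluable"}


class TestMSIBaseline:
    def test_pool_of_identical_histograms(self, panel):
        profiles = [_profile({16: 80, 15: 20}, locus="MSI_01", pid=f"S{i}")
                    for i in range(6)]
        baseline = build_msi_baseline(profiles, panel)
        locus = baseline.loci["MSI_01"]
        assert locus.frequencies == {16: 0.8, 15: 0.2}
        assert locus.support == {16, 15}

    def test_zero_depth_sample_ignored(self, panel):
        profiles = [_profile({16: 100}, locus="MSI_01", pid=f"S{i}")
                    for i in range(5)]
        profiles.append(_profile({}, locus="MSI_01", pid="S9"))
        baseline = build_msi_baseline(profiles, panel)
        assert baseline.loci["MSI_01"].n_samples == 5

    def test_small_pool_is_error(self, panel):
        profiles = [_profile({16: 10}, pid=f"S{i}") for i in range(3)]
        with pytest.raises(ValueError, match="pool"):
            build_msi_baseline(profiles, panel)

    def test_support_floor(self, panel):
        # 0.5% of mass at length 12 stays out of the support set
        profiles = [_profile({16: 995, 12: 5}, locus="MSI_01", pid=f"S{i}")
                    for i in range(6)]
        baseline = build_msi_baseline(profiles, panel)
        assert 12 not in baseline.loci["MSI_01"].support


class TestLocusInstability:
    def test_identical_to_baseline_is_stable(self):
        b = _baseline(["L01"], support_lengths=(16, 15))
        assert score_locus_instability(_profile({16: 80, 15: 20}), b) == "stable"

    def test_full_shift_is_unstable(self):
        b = _baseline(["L01"], support_lengths=(16, 15))
        assert score_locus_instability(_profile({13: 100}), b) == "unstable"

    def test_low_depth_unqualified(self):
        b = _baseline(["L01"])
        assert score_locus_instability(_profile({16: 10}), b) == "unqualified"

    def test_missing_baseline_unqualified(self):
        b = _baseline(["L02"])
        assert score_locus_instability(_profile({16: 100}, locus="L01"), b) \
            == "unqualified"

    def test_mass_cutoff_boundary(self):
        b = _baseline(["L01"])
        # exactly 20% out-of-support mass counts as unstable (>= cutoff)
        assert score_locus_instability(_profile({16: 80, 12: 20}), b) == "unstable"
        assert score_locus_instability(_profile({16: 81, 12: 19}), b) == "stable"


class TestCallMSI:
    def _profiles(self, n_unstable, n_total=52):
        loci = [f"L{i:02d}" for i in range(n_total)]
        profiles = [
            _profile({12: 100} if i < n_unstable else {16: 100}, locus=l)
            for i, l in enumerate(loci)
        ]
        return profiles, _baseline(loci)

    def test_threshold_flip(self):
        profiles, baseline = self._profiles(24)
        assert call_msi(profiles, baseline) == ("MSI", 52, 24)  # 46.2% > 45%
        profiles, baseline = self._profiles(23)
        assert call_msi(profiles, baseline) == ("MSS", 52, 23)  # 44.2%

    def test_not_evaluable_below_min_qualified(self):
        profiles, baseline = self._profiles(2, n_total=5)
        status, n_q, _ = call_msi(profiles, baseline)
        assert status == "not_evaluable" and n_q == 5

    def test_monotone_in_unstable_sites(self):
        # adding an unstable site never flips MSI -> MSS
        for k in range(0, 52):
            profiles, baseline = self._profiles(k)
            s1 = call_msi(profiles, baseline)[0]
            profiles2, baseline2 = self._profiles(k + 1)
            s2 = call_msi(profiles2, baseline2)[0]
            assert not (s1 == "MSI" and s2 == "MSS")
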