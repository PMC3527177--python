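"""The filter cascade and its individual predicates."""

import dataclasses

import pytest

from hetsnp import FilterParams, run_cascade
from hetsnp.filters import (
    fvf_filter,
    homopolymer_filter,
    proximity_filter,
    quality_filters,
    right_edge_filter,
)
from hetsnp.io import ReferenceSeq
from hetsnp.stacks import CandidateSNP


def snp(**kw):
    base = dict(
        ref_id="bes1", pos=100, ref_base="A", allele1="A", allele2="G",
        vf=0.45, fvf=0.45, rmd=20, mqs=34.0, ref_base_quality=50, annotation="genic",
    )
    base.update(kw)
    return CandidateSNP(**base)


def make_ref(length=700, rid="bes1"):
    # homopolymer-free periodic backbone so individual tests control the context
    seq = ("ACGT" * (length // 4 + 1))[:length]
    return ReferenceSeq(rid, seq, [50] * length, annotation="genic")


class TestQualityFilters:
    def test_min_rmd(self):
        assert "min_rmd" in quality_filters(snp(rmd=4), FilterParams.adjusted())

    def test_max_rmd(self):
        assert "max_rmd" in quality_filters(snp(rmd=26), FilterParams.adjusted(max_rmd=25))

    def test_initial_preset_has_no_max_rmd(self):
        assert "max_rmd" not in quality_filters(snp(rmd=500), FilterParams.initial())

    def test_genic_quality_threshold_boundary(self):
        assert quality_filters(snp(ref_base_quality=40), FilterParams.adjusted()) == []
        assert "ref_base_quality" in quality_filters(
            snp(ref_base_quality=39), FilterParams.adjusted()
        )

    def test_unknown_annotation_uses_stricter_threshold(self):
        s = snp(annotation="unknown", ref_base_quality=42)
        assert "ref_base_quality" in quality_filters(s, FilterParams.adjusted())
        s2 = snp(annotation="nongenic", ref_base_quality=45)
        assert quality_filters(s2, FilterParams.adjusted()) == []

    def test_mqs_thresholds_differ_between_presets(self):
        s = snp(mqs=27.0)
        assert quality_filters(s, FilterParams.initial()) == []
        assert "mqs" in quality_filters(s, FilterParams.adjusted())


class TestFvfFilter:
    def test_fixed_threshold(self):
        params = FilterParams.initial()
        assert not fvf_filter(snp(fvf=0.19), params)
        assert fvf_filter(snp(fvf=0.2), params)

    def test_ttest_mode_null_value_passes(self):
        assert fvf_filter(snp(fvf=0.5, rmd=8), FilterParams.adjusted())

    def test_ttest_mode_deviating_fvf_fails(self):
        s = snp(fvf=0.2, rmd=25)
        assert not fvf_filter(s, FilterParams.adjusted())
        assert s.t_stat == pytest.approx(2.8)


class TestHomopolymer:
    def test_inside_run_fails(self):
        ref = ReferenceSeq("bes1", "CTAAAGCT", [50] * 8)
        assert not homopolymer_filter(snp(pos=4, ref_base="A"), ref, FilterParams())

    def test_allele_creating_run_fails(self):
        # ref ...AAG...: substituting A at the G makes AAA
        ref = ReferenceSeq("bes1", "CTAAGTCT", [50] * 8)
        s = snp(pos=5, ref_base="G", allele1="G", allele2="A")
        assert not homopolymer_filter(s, ref, FilterParams())

    def test_clean_context_passes(self):
        ref = ReferenceSeq("bes1", "ACGTACGT", [50] * 8)
        assert homopolymer_filter(snp(pos=3, ref_base="G", allele2="T"), ref, FilterParams())

    def test_out_of_range_is_error(self):
        ref = ReferenceSeq("bes1", "ACGT", [50] * 4)
        with pytest.raises(ValueError):
            homopolymer_filter(snp(pos=9), ref, FilterParams())


class TestProximity:
    def test_pair_at_three_bp_both_fail(self):
        group = [snp(pos=100), snp(pos=103)]
        assert proximity_filter(group, FilterParams()) == {0, 1}

    def test_pair_at_four_bp_pass(self):
        group = [snp(pos=100), snp(pos=104)]
        assert proximity_filter(group, FilterParams()) == set()

    def test_singleton_passes(self):
        assert proximity_filter([snp(pos=100)], FilterParams()) == set()


class TestRightEdge:
    @pytest.mark.parametrize("pos,ok", [(671, False), (670, True), (1, True)])
    def test_boundaries_on_700bp_reference(self, pos, ok):
        ref = make_ref(700)
        assert right_edge_filter(snp(pos=pos), ref, FilterParams()) is ok


class TestCascade:
    def _toy_set(self):
        """Eight candidates, seven with exactly one designed defect."""
        ref = make_ref(700)
        good = dict(ref_id="bes1", annotation="genic")
        candidates = [
            snp(pos=100, **good),                                  # survivor
            snp(pos=200, rmd=4, fvf=0.45, **good),                 # min_rmd
            snp(pos=250, rmd=40, fvf=0.45, **good),                # max_rmd (cutoff 25)
            snp(pos=300, fvf=0.1, rmd=30, **good),                 # fvf t-test
            snp(pos=350, mqs=20.0, **good),                        # mqs
            snp(pos=400, ref_base_quality=30, **good),             # ref_base_quality
            snp(pos=500, **good), snp(pos=502, **good),            # spacing pair
            snp(pos=680, **good),                                  # right_edge (20 bp from end)
        ]
        # homopolymer defect: plant an AAA run at pos 600
        seq = ref.sequence[:599] + "AAA" + ref.sequence[602:]
        ref = ReferenceSeq("bes1", seq, [50] * 700, annotation="genic")
        candidates.append(snp(pos=600, ref_base="A", **good))
        return ref, candidates

    def test_designed_failures_each_caught(self):
        ref, candidates = self._toy_set()
        passed, report = run_cascade(candidates, [ref], FilterParams.adjusted(max_rmd=25))
        assert [s.pos for s in passed] == [100]
        causes = {f for s in candidates for f in s.filter_flags}
        assert causes == {
            "min_rmd", "max_rmd", "fvf", "mqs", "ref_base_quality", "homopolymer",
            "spacing", "right_edge",
        }
        frame = report.to_frame()
        assert (frame["input"] == len(candidates)).all()
        assert (frame["input"] == frame["failed"] + frame["passed"]).all()

    def test_empty_input(self):
        passed, report = run_cascade([], [], FilterParams())
        assert passed == [] and report.n_candidates == 0

    def test_disabled_thresholds_are_identity(self):
        ref, candidates = self._toy_set()
        off = FilterParams(
            min_rmd=0, max_rmd=None, min_mqs=0, min_ref_snp_qual_genic=0,
            min_ref_snp_qual_nongenic=0, homopolymer_len=10**9, min_snp_spacing=0,
            right_edge_bp=0, fvf_mode="fixed_threshold", fvf_threshold=0.0,
        )
        passed, _ = run_cascade(candidates, [ref], off)
        assert len(passed) == len(candidates)

    def test_order_invariance(self):
        ref, candidates = self._toy_set()
        params = FilterParams.adjusted(max_rmd=25)
        a, _ = run_cascade(list(candidates), [ref], params)
        b, _ = run_cascade(list(reversed(candidates)), [ref], params)
        assert [(s.ref_id, s.pos) for s in a] == [(s.ref_id, s.pos) for s in b]

    def test_survivors_satisfy_every_predicate(self, e2e_results):
        cfg, refs, truth, adjusted, _ = e2e_results
        params = dataclasses.replace(
            FilterParams.adjusted(), max_rmd=adjusted.depth_model.cutoff
        )
        ref_map = {r.id: r for r in refs}
        for s in adjusted.passed[:200]:
            assert quality_filters(s, params) == []
            assert fvf_filter(s, params)
            assert homopolymer_filter(s, ref_map[s.ref_id], params)
            assert right_edge_filter(s, ref_map[s.ref_id], params)

    def test_bad_fvf_mode_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(fvf_mode="bogus")
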