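"""Fragment loading, filter metrics, thresholding and library calling."""

import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import techimera as tc
from techimera.detection import (
    DetectionError,
    _count_supporting_fragments,
    apply_thresholds,
    compute_candidate_metrics,
)

GI = tc.GenomicInterval


def frag(chrom, m1, m2, orientation="+", library_id="L"):
    """Build a FragmentAlignment from two ungapped mate spans."""
    b1 = (GI(chrom, *m1),)
    b2 = (GI(chrom, *m2),)
    allb = b1 + b2
    outer = GI(chrom, min(b.start for b in allb), max(b.end for b in allb))
    return tc.FragmentAlignment(
        outer=outer, orientation=orientation, library_id=library_id,
        mate_blocks=(b1, b2),
    )


def make_sam(path, records, chrom_sizes={"chr1": 100_000}):
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)


def make_pair(qname, pos1, pos2, cigar1="50M", cigar2="50M", flag_extra1=0,
              flag_extra2=0, xs=None):
    recs = []
    for i, (pos, cig, extra) in enumerate(
        ((pos1, cigar1, flag_extra1), (pos2, cigar2, flag_extra2))
    ):
        r = pysam.AlignedSegment()
        r.query_name = qname
        r.reference_id = 0
        r.reference_start = pos
        r.cigarstring = cig
        r.mapping_quality = 60
        r.flag |= 1 | 2  # paired, proper
        r.flag |= 64 if i == 0 else 128
        r.flag |= extra
        r.next_reference_id = 0
        r.next_reference_start = pos2 if i == 0 else pos1
        if xs:
            r.set_tag("XS", xs)
        recs.append(r)
    return recs


class TestLoadFragments:
    LIB = tc.Library("L", total_fragments=1)

    def test_proper_pair_collapsed_to_outer_span(self, tmp_path):
        p = tmp_path / "a.sam"
        make_sam(p, make_pair("q1", 100, 300, xs="+"))
        (f,) = tc.load_fragments(p, self.LIB)
        assert (f.outer.start, f.outer.end) == (100, 350)
        assert f.orientation == "+"
        assert not f.spliced

    def test_secondary_and_duplicate_records_excluded(self, tmp_path):
        p = tmp_path / "b.sam"
        recs = make_pair("q1", 100, 300)
        recs += make_pair("q2", 100, 300, flag_extra1=256, flag_extra2=256)
        recs += make_pair("q3", 100, 300, flag_extra1=1024, flag_extra2=1024)
        make_sam(p, recs)
        frags = tc.load_fragments(p, self.LIB)
        assert len(frags) == 1

    def test_spliced_mate_blocks_exclude_skipped_intron(self, tmp_path):
        p = tmp_path / "c.sam"
        make_sam(p, make_pair("q1", 100, 400, cigar2="20M1000N30M"))
        (f,) = tc.load_fragments(p, self.LIB)
        assert f.spliced
        assert f.outer.end == 400 + 20 + 1000 + 30
        # the skipped intron is not part of any mate block
        assert not f.mate_overlaps(GI("chr1", 500, 1000))
        assert f.mate_overlaps(GI("chr1", 400, 420))
        assert f.mate_overlaps(GI("chr1", 1420, 1450))

    def test_unpaired_input_rejected(self, tmp_path):
        p = tmp_path / "d.sam"
        r = pysam.AlignedSegment()
        r.query_name = "q"
        r.reference_id = 0
        r.reference_start = 10
        r.cigarstring = "50M"
        r.flag = 0
        make_sam(p, [r])
        with pytest.raises(DetectionError, match="single-end"):
            tc.load_fragments(p, self.LIB)

    def test_random_sam_matches_flag_walking_oracle(self, tmp_path):
        rng = np.random.default_rng(31)
        recs, expected = [], {}
        for i in range(20):
            a = int(rng.integers(0, 5000))
            b = a + int(rng.integers(60, 400))
            recs.extend(make_pair(f"q{i}", a, b, xs="+" if i % 2 else "-"))
            expected[f"q{i}"] = (a, b + 50)
        p = tmp_path / "r.sam"
        make_sam(p, recs)
        frags = tc.load_fragments(p, self.LIB)
        assert len(frags) == 20
        got = sorted((f.outer.start, f.outer.end) for f in frags)
        assert got == sorted(expected.values())


class TestMinSupportingFragments:
    @pytest.mark.parametrize(
        "total,mode,expected",
        [
            (20_000_000, "relaxed", 3),
            (100_000_000, "stringent", 10),
            (120_000_000, "relaxed", 6),
            (1_000, "stringent", 6),
        ],
    )
    def test_greater_of_base_and_scaled(self, total, mode, expected):
        th = tc.ThresholdSet.from_mode(mode)
        assert tc.min_supporting_fragments(total, th) == expected

    @given(st.integers(min_value=1, max_value=10**9))
    @settings(max_examples=100, deadline=None)
    def test_nondecreasing_and_floor(self, total):
        th = tc.ThresholdSet.relaxed()
        n = tc.min_supporting_fragments(total, th)
        assert n >= th.scREADS
        assert n >= tc.min_supporting_fragments(max(1, total - 1), th)
        if total <= th.scREADS * th.spCOE_divisor:
            assert n == th.scREADS


class TestPerBaseCoverage:
    def test_single_full_overlap(self):
        cov = tc.per_base_coverage([frag("c", (0, 5), (5, 10))], GI("c", 0, 10))
        assert cov.mean == 1.0 and cov.peak == 1.0

    def test_empty(self):
        cov = tc.per_base_coverage([], GI("c", 0, 10))
        assert cov.mean == 0.0 and cov.peak == 0.0

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(17)
        frags = []
        for _ in range(100):
            a = int(rng.integers(0, 900))
            b = a + int(rng.integers(1, 120))
            mid = (a + b) // 2
            frags.append(frag("c", (a, max(a + 1, mid)), (mid, b) if mid < b else (a, b)))
        iv = GI("c", 100, 700)
        cov = tc.per_base_coverage(frags, iv)
        depth = np.zeros(len(iv), dtype=int)
        for f in frags:
            for pos in range(iv.start, iv.end):
                if f.outer.start <= pos < f.outer.end:
                    depth[pos - iv.start] += 1
        assert np.array_equal(cov.depth, depth)
        assert cov.peak == depth.max()
        assert cov.mean == pytest.approx(depth.mean())


def _tx(strand="+", exons=((10_000, 10_500), (13_000, 13_500)), tid="t1", gid="g1"):
    return tc.TranscriptModel(
        tid, gid, strand,
        tuple(GI("chr1", s, e, strand) for s, e in exons),
    )


def _te(start, end, strand="+", eid="te1", te_class="LTR", sub="MaLR"):
    return tc.TEAnnotation(
        interval=GI("chr1", start, end, strand),
        repeat_name="MSTD",
        te_class=te_class,
        ltr_subclass=sub,
        element_id=eid,
    )


class TestDiscoverCandidates:
    def test_tss_inside_te(self):
        tx = _tx(exons=((5_000, 5_400), (8_000, 8_400)))
        cands = tc.discover_candidates([tx], [], [_te(4_800, 5_200)])
        assert len(cands) == 1
        assert cands[0].route == "tss_in_te"

    def test_tss_one_base_outside_te_not_called(self):
        tx = _tx(exons=((5_000, 5_400), (8_000, 8_400)))
        assert tc.discover_candidates([tx], [], [_te(4_800, 5_000)]) == []
        # end of the half-open TE interval is exclusive
        assert len(tc.discover_candidates([tx], [], [_te(4_800, 5_001)])) == 1

    def test_upstream_te_with_bridging_fragments(self):
        tx = _tx()  # first exon (10000, 10500)
        te = _te(7_900, 8_300)
        bridges = [
            frag("chr1", (8_000, 8_100), (10_050, 10_150)) for _ in range(4)
        ]
        (cand,) = tc.discover_candidates([tx], bridges, [te])
        assert cand.route == "upstream_extension"
        assert _count_supporting_fragments(cand, bridges) == 4

    def test_upstream_te_without_bridge_or_too_far(self):
        tx = _tx(exons=((20_000, 20_500), (23_000, 23_500)))
        assert tc.discover_candidates([tx], [], [_te(17_900, 18_300)]) == []
        far = _te(8_000, 8_500)  # 11.5 kb from the first exon
        bridge = [frag("chr1", (8_100, 8_200), (20_050, 20_150))]
        assert tc.discover_candidates([tx], bridge, [far]) == []

    def test_minus_strand_upstream_is_rightward(self):
        tx = _tx(strand="-", exons=((10_000, 10_500), (13_000, 13_500)))
        # first exon is (13000,13500); upstream lies genomically right
        te = _te(14_000, 14_400)
        bridge = [frag("chr1", (13_300, 13_400), (14_050, 14_150))]
        (cand,) = tc.discover_candidates([tx], bridge, [te])
        assert cand.route == "upstream_extension"


class TestFilterMetrics:
    def test_directional_bias_ratios(self):
        cand = tc.ChimeraCandidate(te=_te(4_800, 5_200), transcript=_tx(), route="tss_in_te")
        def mk(n_sense, n_anti):
            fr = [frag("chr1", (4_900, 5_000), (5_000, 5_100), "+") for _ in range(n_sense)]
            fr += [frag("chr1", (4_900, 5_000), (5_000, 5_100), "-") for _ in range(n_anti)]
            return fr
        assert tc.compute_directional_bias(cand, mk(10, 1)) == 10.0
        assert tc.compute_directional_bias(cand, mk(5, 0)) == math.inf
        assert tc.compute_directional_bias(cand, mk(6, 6)) == 1.0
        assert math.isnan(tc.compute_directional_bias(cand, []))
        unknown = [frag("chr1", (4_900, 5_000), (5_000, 5_100), ".")]
        assert math.isnan(tc.compute_directional_bias(cand, unknown))

    @pytest.mark.parametrize(
        "n,length,total,expected",
        [(100, 1_000, 10_000_000, 10.0), (0, 1_000, 10_000_000, 0.0),
         (5, 500, 20_000_000, 0.5)],
    )
    def test_exon_rpkm_formula(self, n, length, total, expected):
        exon = GI("chr1", 10_000, 10_000 + length)
        frags = [frag("chr1", (10_000, 10_050), (10_050, 10_100)) for _ in range(n)]
        lib = tc.Library("L", total_fragments=total)
        assert tc.compute_exon_rpkm(exon, frags, lib) == pytest.approx(expected)

    def test_contribution_shares(self):
        te_tx = _tx(exons=((5_000, 5_400), (13_000, 13_500)), tid="te_iso")
        nat_tx = _tx(exons=((10_000, 10_500), (13_000, 13_500)), tid="nat_iso")
        cand = tc.ChimeraCandidate(te=_te(4_900, 5_500), transcript=te_tx, route="tss_in_te")
        def mk(n_te, n_nat):
            fr = [frag("chr1", (5_100, 5_200), (5_200, 5_300)) for _ in range(n_te)]
            fr += [frag("chr1", (10_100, 10_200), (10_200, 10_300)) for _ in range(n_nat)]
            return fr
        both = [te_tx, nat_tx]
        assert tc.compute_contribution(cand, both, mk(50, 50)) == pytest.approx(0.5)
        assert tc.compute_contribution(cand, both, mk(9, 91)) == pytest.approx(0.09)
        assert tc.compute_contribution(cand, [te_tx], mk(30, 0)) == pytest.approx(1.0)
        assert math.isnan(tc.compute_contribution(cand, both, []))

    def test_contribution_pools_reciprocally_overlapping_first_exons(self):
        te_tx = _tx(exons=((5_000, 5_400), (13_000, 13_500)), tid="te_iso")
        nat1 = _tx(exons=((10_000, 10_500), (13_000, 13_500)), tid="n1")
        nat2 = _tx(exons=((10_050, 10_520), (13_000, 13_500)), tid="n2")
        cand = tc.ChimeraCandidate(te=_te(4_900, 5_500), transcript=te_tx, route="tss_in_te")
        frags = [frag("chr1", (5_100, 5_200), (5_200, 5_300)) for _ in range(30)]
        frags += [frag("chr1", (10_100, 10_200), (10_200, 10_300)) for _ in range(30)]
        # the two native first exons overlap >50% reciprocally: one promoter
        got = tc.compute_contribution(cand, [te_tx, nat1, nat2], frags)
        assert got == pytest.approx(0.5)

    def test_upstream_coverage_ratio_conventions(self):
        te = _te(1_000, 2_000)
        cand = tc.ChimeraCandidate(te=te, transcript=_tx(), route="tss_in_te")
        te_frags = [frag("chr1", (1_000, 1_500), (1_500, 2_000)) for _ in range(3)]
        up_frags = [frag("chr1", (0, 500), (500, 1_000))]
        ratio, _ = tc.compute_upstream_coverage_ratio(cand, te_frags + up_frags)
        assert ratio == pytest.approx(3.0)
        ratio, _ = tc.compute_upstream_coverage_ratio(cand, te_frags)
        assert ratio == math.inf
        te_at_edge = _te(0, 600)
        cand2 = tc.ChimeraCandidate(te=te_at_edge, transcript=_tx(), route="tss_in_te")
        ratio, flags = tc.compute_upstream_coverage_ratio(
            cand2, [frag("chr1", (0, 300), (300, 600))]
        )
        assert ratio == math.inf and "no_upstream_window" in flags

    def test_upstream_exon_ratio_and_vacuous_pass(self):
        lib = tc.Library("L", total_fragments=1_000_000)
        # TE-resident first exon at (5000,5400); native exons share downstream
        te_tx = tc.TranscriptModel(
            "te_iso", "g1", "+",
            (GI("chr1", 5_000, 5_400, "+"), GI("chr1", 13_000, 13_400, "+")),
        )
        nat_tx = tc.TranscriptModel(
            "nat_iso", "g1", "+",
            (GI("chr1", 2_000, 2_400, "+"), GI("chr1", 13_000, 13_400, "+")),
        )
        cand = tc.ChimeraCandidate(te=_te(4_900, 5_500), transcript=te_tx, route="tss_in_te")
        def mk(n_up, n_te):
            fr = [frag("chr1", (2_100, 2_150), (2_200, 2_250)) for _ in range(n_up)]
            fr += [frag("chr1", (5_100, 5_150), (5_200, 5_250)) for _ in range(n_te)]
            return fr
        r = tc.compute_upstream_exon_ratio(cand, [te_tx, nat_tx], mk(10, 10), lib)
        assert r == pytest.approx(1.0)
        r = tc.compute_upstream_exon_ratio(cand, [te_tx, nat_tx], mk(30, 10), lib)
        assert r == pytest.approx(3.0)
        # no upstream exons at all: filter not applicable
        r = tc.compute_upstream_exon_ratio(cand, [te_tx], mk(0, 10), lib)
        assert r is None
        r = tc.compute_upstream_exon_ratio(cand, [te_tx, nat_tx], mk(10, 0), lib)
        assert r == math.inf


def _candidate_with_metrics(n=6, bias=10.0, rpkm=1.0, contr=0.5, upcov=3.0,
                            upexon=1.0):
    cand = tc.ChimeraCandidate(te=_te(4_800, 5_200), transcript=_tx(), route="tss_in_te")
    cand.n_supporting_fragments = n
    cand.directional_bias = bias
    cand.exon_rpkm = rpkm
    cand.contribution = contr
    cand.upstream_cov_ratio = upcov
    cand.upstream_exon_ratio = upexon
    return cand


class TestApplyThresholds:
    LIB = tc.Library("L", total_fragments=20_000_000)

    def test_all_stringent_boundaries_accept(self):
        cand = _candidate_with_metrics()
        out = apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)
        assert out.accepted and all(out.verdicts.values())

    def test_single_failing_metric_named(self):
        cand = _candidate_with_metrics(contr=0.49)
        out = apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)
        assert not out.accepted
        failed = [k for k, v in out.verdicts.items() if not v]
        assert failed == ["contribution"]

    def test_relaxed_boundaries_accept_relaxed_only(self):
        cand = _candidate_with_metrics(n=3, bias=5.0, contr=0.1, upcov=2.0)
        assert apply_thresholds(cand, tc.ThresholdSet.relaxed(), self.LIB).accepted
        cand = _candidate_with_metrics(n=3, bias=5.0, contr=0.1, upcov=2.0)
        assert not apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB).accepted

    def test_upexon_is_strictly_less_than(self):
        cand = _candidate_with_metrics(upexon=1.5)
        out = apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)
        assert not out.verdicts["upexon"]
        cand = _candidate_with_metrics(upexon=None)
        cand.upstream_exon_ratio = None
        out = apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)
        assert out.verdicts["upexon"]

    def test_infinite_ratios_pass_nan_fails(self):
        cand = _candidate_with_metrics(bias=math.inf, upcov=math.inf)
        assert apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB).accepted
        cand = _candidate_with_metrics(bias=math.nan)
        out = apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)
        assert not out.verdicts["bias"]

    def test_missing_metric_is_an_error(self):
        cand = tc.ChimeraCandidate(te=_te(4_800, 5_200), transcript=_tx(),
                                   route="tss_in_te")
        with pytest.raises(DetectionError, match="n_supporting_fragments"):
            apply_thresholds(cand, tc.ThresholdSet.stringent(), self.LIB)


class TestCallLibrary:
    def _calls(self, result, gtf_transcripts, merged_tes, mode):
        cs = tc.call_library(
            gtf_transcripts, result.fragments, merged_tes, result.library,
            tc.ThresholdSet.from_mode(mode),
        )
        return {(c.te.element_id, c.transcript.transcript_id) for c in cs.calls}

    @pytest.mark.parametrize("mode", ["relaxed", "stringent"])
    def test_calls_match_planted_truth(self, cancer_result, gtf_transcripts,
                                       merged_tes, mode):
        got = self._calls(cancer_result, gtf_transcripts, merged_tes, mode)
        expected = {
            (t.element_id, t.transcript_id)
            for t in cancer_result.truth
            if t.expected_accept(mode)
        }
        assert got == expected

    def test_all_native_fixture_yields_zero_calls(self):
        specs = tuple(
            tc.GeneSpec(f"g{i}", "none", te_fraction=0.0) for i in range(4)
        )
        cfg = tc.SimulationConfig(seed=5, n_pairs=1, genes=specs)
        fx = tc.build_fixture_genome(cfg)
        res = tc.simulate_library(fx, "L", "p", "cancer", np.random.SeedSequence(1))
        cs = tc.call_library(
            fx.gtf_transcripts(), res.fragments,
            tc.merge_fragmented_elements(fx.te_annotations()),
            res.library, tc.ThresholdSet.relaxed(),
        )
        assert cs.calls == []

    def test_stringent_subset_of_relaxed(self, cancer_result, normal_result,
                                         gtf_transcripts, merged_tes):
        for result in (cancer_result, normal_result):
            stringent = self._calls(result, gtf_transcripts, merged_tes, "stringent")
            relaxed = self._calls(result, gtf_transcripts, merged_tes, "relaxed")
            assert stringent <= relaxed

    def test_call_tsv_deterministic(self, tmp_path, cancer_result,
                                    gtf_transcripts, merged_tes):
        cs = tc.call_library(
            gtf_transcripts, cancer_result.fragments, merged_tes,
            cancer_result.library, tc.ThresholdSet.stringent(),
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        tc.write_calls(cs, p1)
        cs2 = tc.call_library(
            gtf_transcripts, cancer_result.fragments, merged_tes,
            cancer_result.library, tc.ThresholdSet.stringent(),
        )
        tc.write_calls(cs2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        df = tc.read_calls(p1)
        assert list(df.columns) == tc.detection.CALL_COLUMNS
        assert (df["accepted"] == 1).sum() == len(cs.calls)


def test_rpkm_invariant_under_depth_scaling():
    exon = GI("chr1", 0, 1_000)
    frags = [frag("chr1", (0, 50), (100, 150)) for _ in range(40)]
    lib1 = tc.Library("a", total_fragments=1_000_000)
    lib3 = tc.Library("b", total_fragments=3_000_000)
    r1 = tc.compute_exon_rpkm(exon, frags, lib1)
    r3 = tc.compute_exon_rpkm(exon, frags * 3, lib3)
    assert r1 == pytest.approx(r3)
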