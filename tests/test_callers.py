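"""Read filtering, start-signal extraction and single-base site calling."""

import numpy as np
import pandas as pd
import pytest

import dmnseq as d
from dmnseq.callers import (
    call_sites,
    extract_start_signals,
    intensity_vs_beta,
    pfm_around_sites,
    prefix_filter,
    replicate_correlation,
)
from dmnseq.genome import Methylome, ReferenceGenome
from dmnseq.simulate import SimParams


def _placements(rows):
    return pd.DataFrame(rows, columns=["contig", "r1_start", "r1_end", "strand"])


class TestPrefixFilter:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAGCTT", (True, 3)),
        ("AAGCTT", (False, 0)),
        ("AAAAGC", (True, 3)),   # 4th A is genomic, trimmed exactly k
        ("AA", (False, 0)),      # shorter than k
    ])
    def test_examples(self, seq, expected):
        assert prefix_filter(seq, k=3) == expected

    def test_custom_tag_and_invalid_k(self):
        assert prefix_filter("TTTGCA", k=3, tag_base="T") == (True, 3)
        with pytest.raises(ValueError):
            prefix_filter("AAA", k=0)


class TestExtractStartSignals:
    def test_plus_strand_counts_and_offset(self):
        sig = extract_start_signals(
            _placements([("c", 101, 200, "+")] * 3), offset=1)
        assert sig.to_dict("records") == [
            {"contig": "c", "pos": 100, "strand": "+", "intensity": 3}]

    def test_minus_strand_five_prime_is_rightmost_base(self):
        # alignment [50,100): 5' end at 99, site = 99 + 1 = 100
        sig = extract_start_signals(_placements([("c", 50, 100, "-")]), offset=1)
        assert sig.to_dict("records") == [
            {"contig": "c", "pos": 100, "strand": "-", "intensity": 1}]

    def test_strandless_records_dropped_with_warning(self, caplog):
        sig = extract_start_signals(
            _placements([("c", 10, 50, "+"), ("c", 10, 50, ".")]), offset=0)
        assert sig["intensity"].sum() == 1

    def test_dedup_collapses_identical_alignments(self):
        rows = [("c", 10, 50, "+")] * 4 + [("c", 10, 60, "+")]
        assert extract_start_signals(_placements(rows), offset=0,
                                     dedup=True)["intensity"].sum() == 2
        assert extract_start_signals(_placements(rows), offset=0,
                                     dedup=False)["intensity"].sum() == 5

    def test_conservation_sum_equals_read_count(self, lambda_replicates):
        lib_a, _lib_b, sig_a, _sig_b = lambda_replicates
        assert sig_a["intensity"].sum() == len(lib_a)


class TestCallSites:
    def test_threshold_and_monotonicity(self, small_genome):
        sig = pd.DataFrame({"contig": "contig_1", "pos": [10, 20],
                            "strand": "+", "intensity": [5, 4]})
        called5 = call_sites(sig, small_genome, min_intensity=5)
        called1 = call_sites(sig, small_genome, min_intensity=1)
        assert len(called5) == 1 and called5["pos"].iloc[0] == 10
        assert len(called1) == 2
        assert set(map(tuple, called5[["contig", "pos"]].values)) <= \
            set(map(tuple, called1[["contig", "pos"]].values))

    def test_nick_site_oracle_equivalence_without_background(self):
        """With p_bg = 0 the called set at threshold 1 is exactly the truth
        nick-site set with >= 1 surviving piece."""
        g = d.gen_genome(1, 20_000, 0.5, seed=300, n_dcm=120)
        me = d.gen_lambda_like_methylome(g, ("uniform", 0.2, 0.9), seed=301)
        lib = d.build_dmnplus_library(g, me, SimParams(depth=60, p_bg=0.0, seed=302))
        sig = extract_start_signals(lib.truth, offset=1)
        called = call_sites(sig, g, min_intensity=1)
        got = set(map(tuple, called[["contig", "pos", "strand"]].values))
        expected = set(zip(lib.truth["contig"], lib.truth["nick_pos"],
                           lib.truth["strand"]))
        assert got == expected
        assert got <= set(me.sites)  # every call is a true methylated site


class TestIntensityVsBeta:
    def test_exact_linear_gives_r_one(self, small_genome):
        me = Methylome()
        positions = [p for p in range(100, 400)
                     if small_genome.base_at("contig_1", p, "+") == "C"][:5]
        for i, p in enumerate(positions):
            me.add_site(d.MethylSite("contig_1", p, "+", (i + 1) / 10))
        called = pd.DataFrame({"contig": "contig_1", "pos": positions,
                               "strand": "+",
                               "intensity": [10 * (i + 1) / 10 for i in range(5)]})
        _table, r = intensity_vs_beta(called, me)
        assert r == pytest.approx(1.0)

    def test_constant_intensity_is_an_error(self, small_genome):
        me = Methylome()
        positions = [p for p in range(100, 400)
                     if small_genome.base_at("contig_1", p, "+") == "C"][:4]
        for i, p in enumerate(positions):
            me.add_site(d.MethylSite("contig_1", p, "+", (i + 1) / 10))
        called = pd.DataFrame({"contig": "contig_1", "pos": positions,
                               "strand": "+", "intensity": [7, 7, 7, 7]})
        with pytest.raises(ValueError, match="zero variance"):
            intensity_vs_beta(called, me)

    def test_too_few_overlapping_sites(self):
        me = Methylome()
        me.add_site(d.MethylSite("c", 5, "+", 0.5))
        called = pd.DataFrame({"contig": ["c"], "pos": [5], "strand": ["+"],
                               "intensity": [3]})
        with pytest.raises(ValueError, match="need >= 3"):
            intensity_vs_beta(called, me)


class TestReplicateCorrelation:
    def test_identical_maps(self):
        sig = pd.DataFrame({"contig": "c", "pos": [1, 2, 3], "strand": "+",
                            "intensity": [5, 9, 2]})
        assert replicate_correlation(sig, sig) == pytest.approx(1.0)

    def test_disjoint_sites_anticorrelate_under_union(self):
        a = pd.DataFrame({"contig": "c", "pos": [1, 2], "strand": "+",
                          "intensity": [5, 5]})
        b = pd.DataFrame({"contig": "c", "pos": [3, 4], "strand": "+",
                          "intensity": [5, 5]})
        assert replicate_correlation(a, b, "union") <= 0

    def test_intersection_mode_requires_shared_sites(self):
        a = pd.DataFrame({"contig": "c", "pos": [1, 2], "strand": "+",
                          "intensity": [5, 5]})
        b = pd.DataFrame({"contig": "c", "pos": [3, 4], "strand": "+",
                          "intensity": [5, 5]})
        with pytest.raises(ValueError, match="joined sites"):
            replicate_correlation(a, b, "intersection")


class TestPfm:
    def test_single_site_gives_indicator_matrix(self):
        g = ReferenceGenome([("c", "AATCGGA")])
        called = pd.DataFrame({"contig": ["c"], "pos": [3], "strand": ["+"],
                               "intensity": [9]})
        pfm, skipped = pfm_around_sites(g, called, flank=2)
        assert skipped == 0
        assert set(np.unique(pfm.to_numpy())) <= {0.0, 1.0}
        assert pfm.loc["C", 0] == 1.0 and pfm.loc["G", 1] == 1.0

    def test_minus_strand_site_reverse_complemented(self):
        g = ReferenceGenome([("c", "AACGTTT")])  # (-)-strand C at pos 3
        called = pd.DataFrame({"contig": ["c"], "pos": [3], "strand": ["-"],
                               "intensity": [9]})
        pfm, _ = pfm_around_sites(g, called, flank=1)
        assert pfm.loc["C", 0] == 1.0 and pfm.loc["G", 1] == 1.0

    def test_edge_sites_skipped_and_counted(self):
        g = ReferenceGenome([("c", "CGAAACGAAA")])
        called = pd.DataFrame({"contig": "c", "pos": [0, 5], "strand": "+",
                               "intensity": [9, 9]})
        pfm, skipped = pfm_around_sites(g, called, flank=3)
        assert skipped == 1

    def test_dcm_simulation_recovers_ccwgg_composition(self):
        g = d.gen_genome(1, 30_000, 0.5, seed=310, n_dcm=150)
        me = d.gen_lambda_like_methylome(g, ("fixed", 0.9), seed=311)
        lib = d.build_dmnplus_library(g, me, SimParams(depth=80, p_bg=0.0, seed=312))
        called = call_sites(extract_start_signals(lib.truth, offset=1), g, 5)
        pfm, _ = pfm_around_sites(g, called, flank=3)
        # internal C of CCWGG: columns -1..+3 read C, C, W, G, G
        assert pfm.loc["C", -1] > 0.95 and pfm.loc["C", 0] == 1.0
        assert pfm.loc["A", 1] + pfm.loc["T", 1] > 0.95
        assert pfm.loc["G", 2] > 0.95 and pfm.loc["G", 3] > 0.95

    def test_cpg_simulation_center_is_cg(self):
        g, me = _small_cpg_scenario()
        lib = d.build_dmnplus_library(g, me, SimParams(depth=60, p_bg=0.0, seed=313))
        called = call_sites(extract_start_signals(lib.truth, offset=1), g, 5)
        pfm, _ = pfm_around_sites(g, called, flank=2)
        assert pfm.loc["C", 0] == 1.0
        assert pfm.loc["G", 1] == 1.0


def _small_cpg_scenario():
    from dmnseq.genome import scan_cpg_dyads

    g = d.gen_genome(1, 20_000, 0.5, seed=320)
    me = Methylome()
    for c, p, q in scan_cpg_dyads(g):
        me.add_dyad(c, p, q, 0.8)
    return g, me


def test_sam_roundtrip_matches_truth_signals(tmp_path):
    g, me = _small_cpg_scenario()
    lib = d.build_dmnplus_library(g, me, SimParams(depth=10, seed=330))
    sam = tmp_path / "reads.sam"
    lib.write_sam(sam)
    from_sam = extract_start_signals(sam, offset=1)
    from_truth = extract_start_signals(lib.truth, offset=1)
    pd.testing.assert_frame_equal(from_sam, from_truth)
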