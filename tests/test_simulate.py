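"""Chemistry simulator: fragmentation, realization, nicking, library builds."""

import numpy as np
import pytest
from scipy import stats

import dmnseq as d
from dmnseq.genome import Methylome, MethylSite, ReferenceGenome
from dmnseq.simulate import SimParams, build_bisulfite_truth, dme_nick, fragmentize, realize_molecule


def _flat_genome(length=20_000, seed=200):
    return d.gen_genome(1, length, 0.5, seed=seed)


def _single_site_methylome(pos, strand="+", beta=1.0, mod="5mC"):
    me = Methylome()
    me.add_site(MethylSite("contig_1", pos, strand, beta, mod))
    return me


class TestSimParams:
    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="p_nick"):
            SimParams(p_nick=1.5)
        with pytest.raises(ValueError, match="size_select"):
            SimParams(size_select=(500, 100))
        with pytest.raises(ValueError, match="min_frag_len"):
            SimParams(min_frag_len=1000, frag_len_mean=300)


class TestFragmentize:
    def test_zero_depth_gives_zero_fragments(self):
        g = _flat_genome()
        frags = fragmentize(g, SimParams(depth=1e-9), np.random.default_rng(1))
        assert len(frags) == 0

    def test_min_length_respected(self):
        g = _flat_genome()
        p = SimParams(depth=5, frag_len_mean=100, frag_len_sd=80, min_frag_len=60)
        frags = fragmentize(g, p, np.random.default_rng(1))
        inner = frags[frags["end"] < g.length("contig_1")]
        assert ((inner["end"] - inner["start"]) >= 60).all()

    def test_mean_length_matches_truncated_normal_oracle(self):
        g = _flat_genome(length=200_000)
        p = SimParams(depth=20, frag_len_mean=350, frag_len_sd=70, min_frag_len=30)
        frags = fragmentize(g, p, np.random.default_rng(2))
        lens = (frags["end"] - frags["start"]).to_numpy()
        a = (30 - 350) / 70
        expected = stats.truncnorm(a, np.inf, loc=350, scale=70).mean()
        se = lens.std() / np.sqrt(len(lens))
        # contig-end clipping shortens a ~L_frag/L_contig share of fragments
        assert abs(lens.mean() - expected) < 3 * se + 2


class TestRealizeMolecule:
    def test_beta_extremes(self):
        me = Methylome()
        me.add_dyad("contig_1", 100, 101, 1.0)
        rng = np.random.default_rng(3)
        mol = realize_molecule(("contig_1", 50, 150), me, rng)
        assert {(p, s) for p, s, _m in mol.mods} == {(100, "+"), (101, "-")}
        me0 = Methylome()
        me0.add_dyad("contig_1", 100, 101, 0.0)
        assert realize_molecule(("contig_1", 50, 150), me0, rng).mods == []

    def test_binomial_oracle_at_beta_04(self):
        me = _single_site_methylome(100, beta=0.4)
        rng = np.random.default_rng(4)
        n = 10_000
        hits = sum(bool(realize_molecule(("contig_1", 50, 150), me, rng).mods)
                   for _ in range(n))
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(hits / n - 0.4) < 3 * se

    def test_dyad_realized_jointly(self):
        me = Methylome()
        me.add_dyad("contig_1", 100, 101, 0.5)
        rng = np.random.default_rng(5)
        for _ in range(200):
            mods = realize_molecule(("contig_1", 50, 150), me, rng).mods
            assert len(mods) in (0, 2)


class TestDmeNick:
    def test_certain_nick_at_single_5mc(self):
        me = _single_site_methylome(100)
        rng = np.random.default_rng(6)
        mol = realize_molecule(("contig_1", 50, 150), me, rng)
        nicked = dme_nick(mol, SimParams(p_nick=1.0, p_bg=0.0), rng)
        assert nicked.nicks == [(100, "+")]

    def test_5hmc_never_nicked(self):
        me = _single_site_methylome(100, mod="5hmC")
        rng = np.random.default_rng(7)
        for _ in range(50):
            mol = realize_molecule(("contig_1", 50, 150), me, rng)
            assert dme_nick(mol, SimParams(p_nick=1.0, p_bg=0.0), rng).nicks == []

    def test_symmetric_dyad_cleaves_exactly_one_strand(self):
        me = Methylome()
        me.add_dyad("contig_1", 100, 102, 1.0)  # Dcm-style spacing
        rng = np.random.default_rng(8)
        p = SimParams(p_nick=1.0, p_bg=0.0)
        strands = []
        for _ in range(10_000):
            mol = realize_molecule(("contig_1", 50, 150), me, rng)
            nicks = dme_nick(mol, p, rng).nicks
            assert len(nicks) == 1
            strands.append(nicks[0][1])
        frac_plus = strands.count("+") / len(strands)
        assert abs(frac_plus - 0.5) < 3 * np.sqrt(0.25 / len(strands))


class TestDmnPlusLibrary:
    def test_unmethylated_genome_gives_empty_library(self):
        g = _flat_genome()
        lib = d.build_dmnplus_library(g, Methylome(),
                                      SimParams(depth=20, p_bg=0.0, seed=1))
        assert len(lib) == 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_single_site_read_geometry(self, strand):
        """β/δ-elimination removes the C: the piece 5' terminus is 1 nt 3'."""
        g = _flat_genome()
        m = 10_000
        me = _single_site_methylome(m, strand=strand)
        p = SimParams(depth=150, p_nick=1.0, p_bg=0.0, seed=2)
        lib = d.build_dmnplus_library(g, me, p)
        t = lib.truth
        assert len(t) > 50
        assert (t["nick_pos"] == m).all()
        if strand == "+":
            assert (t["r1_start"] == m + 1).all()
        else:
            assert (t["r1_end"] == m).all()  # rightmost base at m-1
        sig = d.extract_start_signals(t, offset=1)
        assert sig["pos"].tolist() == [m]
        assert sig["strand"].tolist() == [strand]

    def test_seed_determinism_bytes(self, tmp_path):
        g = _flat_genome(5000)
        me = d.gen_lambda_like_methylome(
            d.gen_genome(1, 5000, 0.5, seed=200), ("uniform", 0.1, 0.9), seed=9)
        p = SimParams(depth=50, seed=42)
        paths = []
        for run in ("a", "b"):
            lib = d.build_dmnplus_library(g, me, p)
            r1, r2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
            lib.write_fastq(r1, r2)
            paths.append((r1.read_bytes(), r2.read_bytes()))
        assert paths[0] == paths[1]
        assert len(paths[0][0]) > 0

    def test_dose_response_monotone_in_p_nick(self):
        g = d.gen_genome(1, 20_000, 0.5, seed=210, n_dcm=100)
        me = d.gen_lambda_like_methylome(g, ("fixed", 0.8), seed=211)
        means = []
        for p_nick in (0.1, 0.3, 0.6, 0.9):
            lib = d.build_dmnplus_library(
                g, me, SimParams(depth=40, p_nick=p_nick, p_bg=0.0, seed=12))
            means.append(len(lib))
        assert means == sorted(means)

    def test_read_ids_unique_and_reads_start_with_tag(self):
        g = _flat_genome(5000)
        me = _single_site_methylome(2500, beta=1.0)
        lib = d.build_dmnplus_library(g, me, SimParams(depth=20, p_nick=1.0,
                                                       p_bg=0.0, seed=3))
        ids = lib.truth["read_id"]
        assert ids.is_unique
        for i, (_name, r1, _r2) in enumerate(lib.iter_read_pairs()):
            assert r1.startswith("AAA")
            if i > 50:
                break

    def test_background_nick_rate_matches_p_bg(self):
        g = _flat_genome(50_000)
        p = SimParams(depth=20, p_bg=1e-4, min_frag_len=1, seed=13)
        lib = d.build_dmnplus_library(g, Methylome(), p)
        assert lib.truth["is_background"].all()
        # expected nicks = 2 strands * (depth * contig_len) bases * p_bg
        expected = 2 * 20 * 50_000 * 1e-4
        assert abs(len(lib) - expected) < 4 * np.sqrt(expected) + 0.05 * expected


class TestDmnMinusLibrary:
    def _scenario(self, beta, seed=14, length=30_000):
        g = d.gen_genome(1, length, 0.4, seed=220)
        me = Methylome()
        from dmnseq.genome import scan_cpg_dyads

        for c, p, q in scan_cpg_dyads(g):
            me.add_dyad(c, p, q, beta)
        return g, me

    def test_methylated_molecules_removed(self):
        g, me = self._scenario(beta=1.0)
        p = SimParams(depth=10, size_select=(50, 2000), min_frag_len=30, seed=15)
        lib = d.build_dmnminus_library(g, me, p, treated=True)
        survivors = lib.read_rows()
        assert (~survivors["had_5mC"]).all()

    def test_untreated_keeps_methylated_fragments(self):
        # methylate only the first half of the genome so both kinds exist
        g = d.gen_genome(1, 30_000, 0.4, seed=220)
        from dmnseq.genome import scan_cpg_dyads

        me = Methylome()
        for c, cp, q in scan_cpg_dyads(g):
            if cp < 15_000:
                me.add_dyad(c, cp, q, 1.0)
        p = SimParams(depth=10, size_select=(50, 2000), seed=15)
        lib = d.build_dmnminus_library(g, me, p, treated=False)
        survivors = lib.read_rows()
        assert survivors["had_5mC"].any() and (~survivors["had_5mC"]).any()

    def test_escape_probability_sets_survival_ratio(self):
        g, me = self._scenario(beta=1.0, length=60_000)
        p = SimParams(depth=30, size_select=(50, 2000), epsilon_escape=0.1, seed=16)
        treated = d.build_dmnminus_library(g, me, p, treated=True)
        untreated = d.build_dmnminus_library(g, me, p, treated=False)
        methylated = treated.truth["had_5mC"]
        ratio = (treated.truth.loc[methylated, "fate"] == "amplified_minus_lib").mean()
        assert abs(ratio - 0.1) < 4 * np.sqrt(0.1 * 0.9 / methylated.sum())
        assert len(untreated) > len(treated)

    def test_size_selection_bounds(self):
        g, me = self._scenario(beta=0.0)
        p = SimParams(depth=10, frag_len_mean=150, frag_len_sd=60,
                      min_frag_len=30, size_select=(120, 200), seed=17)
        lib = d.build_dmnminus_library(g, me, p, treated=True)
        lens = lib.read_rows()["frag_end"] - lib.read_rows()["frag_start"]
        assert lens.between(120, 200).all()


class TestBisulfiteTruth:
    def _run(self, beta, depth=80, seed=18):
        g = d.gen_genome(1, 10_000, 0.5, seed=230)
        me = Methylome()
        from dmnseq.genome import scan_cpg_dyads

        for c, p, q in scan_cpg_dyads(g):
            me.add_dyad(c, p, q, beta)
        return build_bisulfite_truth(g, me, SimParams(depth=depth, seed=seed))

    def test_beta_extremes(self):
        t0 = self._run(0.0)
        assert (t0["unconverted"] == 0).all()
        t1 = self._run(1.0)
        assert (t1["unconverted"] == t1["total"]).all()

    def test_ratio_recovers_beta_within_binomial_ci(self):
        t = self._run(0.3, depth=80)
        deep = t[t["total"] >= 50]
        assert len(deep) > 100
        pooled = deep["unconverted"].sum() / deep["total"].sum()
        se = np.sqrt(0.3 * 0.7 / deep["total"].sum())
        assert abs(pooled - 0.3) < 3 * se
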