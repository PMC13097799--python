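"""Forward simulation of glycosylase nicking libraries.

The generative model follows the assay chemistry: double-stranded fragments
are drawn from the genome; each methylation unit (a symmetric dyad or a lone
modified cytosine) inside a fragment is realized methylated on that molecule
with probability beta; the glycosylase excises realized 5mC (never 5hmC) with
probability ``p_nick``, cleaving at most one strand of a symmetric dyad per
molecule; the excised nucleotide is removed, so the downstream piece's 5'
terminus sits one nucleotide 3' of the nicked C along the nicked strand.

Two library designs are built on top of the nicking model:

* the positive design amplifies only pieces whose 5' end was created by an
  excision nick, so read-1 start positions map 5mC at single-base resolution;
* the negative design depletes any molecule carrying at least one realized
  5mC, enriching DNA truly free of methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Methylome, ReferenceGenome, revcomp

__all__ = [
    "SimParams",
    "MoleculeEvent",
    "SimReadSet",
    "fragmentize",
    "realize_molecule",
    "dme_nick",
    "build_dmnplus_library",
    "build_dmnminus_library",
    "build_bisulfite_truth",
]


@dataclass
class SimParams:
    """Tunable knobs of the library simulation.

    ``depth`` is the expected fold-coverage (fragments per contig are drawn
    Poisson with mean ``depth * contig_len / frag_len_mean``).  ``p_nick`` is
    the per-molecule excision probability at a realized 5mC; ``p_bg`` the
    nonspecific nick probability per base per strand.  ``epsilon_escape`` is
    the probability a methylated molecule survives the depletion design.
    ``prefix_tag`` is the adaptor-derived run of bases at the start of read 1
    and ``offset`` the strand-aware correction subtracted when mapping a read
    5' start back to the excised cytosine.
    """

    frag_len_mean: float = 350.0
    frag_len_sd: float = 70.0
    min_frag_len: int = 30
    depth: float = 30.0
    p_nick: float = 0.5
    p_bg: float = 1e-6
    epsilon_escape: float = 0.0
    read_len: int = 100
    prefix_tag: str = "AAA"
    offset: int = 1
    size_select: tuple[int, int] = (100, 1000)
    seed: int = 0

    def __post_init__(self):
        for name in ("p_nick", "p_bg", "epsilon_escape"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_frag_len > self.frag_len_mean:
            raise ValueError("min_frag_len must not exceed frag_len_mean")
        lo, hi = self.size_select
        if lo >= hi:
            raise ValueError("size_select lower bound must be below the upper bound")
        if self.offset not in (0, 1):
            raise ValueError("offset must be 0 or 1")


@dataclass
class MoleculeEvent:
    """One double-stranded fragment with realized mod states and nicks."""

    contig: str
    start: int
    end: int
    mods: list = field(default_factory=list)   # (pos, strand, base_mod)
    nicks: list = field(default_factory=list)  # (pos, strand)
    fate: str = "input"


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _ranges(counts: np.ndarray) -> np.ndarray:
    """arange within each group: [0..c0), [0..c1), ... concatenated."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    return np.arange(total) - np.repeat(ends - counts, counts)


def fragmentize(genome: ReferenceGenome, params: SimParams,
                rng: np.random.Generator) -> pd.DataFrame:
    """Random fragmentation: uniform starts, truncated-normal lengths.

    Lengths are truncated below at ``min_frag_len`` and above at the contig
    end.  Returns a DataFrame of (contig, start, end).
    """
    frames = []
    for contig, seq in genome.items():
        clen = len(seq)
        n = rng.poisson(params.depth * clen / params.frag_len_mean)
        if n == 0:
            continue
        starts = rng.integers(0, clen, size=n)
        lens = np.maximum(
            np.rint(rng.normal(params.frag_len_mean, params.frag_len_sd, size=n)),
            params.min_frag_len,
        ).astype(np.int64)
        ends = np.minimum(starts + lens, clen)
        frames.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame({"contig": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return pd.concat(frames, ignore_index=True)


def _pair_mods(mods):
    """Group realized mods into dyad pairs (opposite strands, <=2 bp apart)."""
    units, used = [], set()
    mods = sorted(mods)
    index = {(p, s): (p, s, m) for p, s, m in mods}
    for p, s, m in mods:
        if (p, s) in used:
            continue
        if s == "+":
            for d in (1, 2):
                partner = index.get((p + d, "-"))
                if partner is not None and (p + d, "-") not in used and partner[2] == m:
                    units.append(((p, s, m), partner))
                    used.update({(p, s), (p + d, "-")})
                    break
            else:
                units.append(((p, s, m),))
                used.add((p, s))
        else:
            units.append(((p, s, m),))
            used.add((p, s))
    return units


def realize_molecule(fragment, methylome: Methylome,
                     rng: np.random.Generator) -> MoleculeEvent:
    """Sample the per-molecule methylation state of one fragment.

    Dyads registered in the methylome are realized jointly (both strand
    cytosines methylated with probability beta, neither otherwise); lone
    sites realize independently.  Units are only realized when they lie
    entirely inside the fragment.
    """
    contig, start, end = fragment
    mods = []
    for a, b in methylome.dyads:
        sa, sb = methylome.sites[a], methylome.sites[b]
        if sa.contig != contig:
            continue
        lo, hi = min(sa.pos, sb.pos), max(sa.pos, sb.pos)
        if start <= lo and hi < end and rng.random() < sa.beta:
            mods.append((sa.pos, sa.strand, sa.base_mod))
            mods.append((sb.pos, sb.strand, sb.base_mod))
    for s in methylome.singles():
        if s.contig == contig and start <= s.pos < end and rng.random() < s.beta:
            mods.append((s.pos, s.strand, s.base_mod))
    return MoleculeEvent(contig, start, end, mods=sorted(mods))


def dme_nick(molecule: MoleculeEvent, params: SimParams,
             rng: np.random.Generator) -> MoleculeEvent:
    """Apply glycosylase excision and background nicking to one molecule.

    Each realized 5mC unit is nicked with probability ``p_nick``; for a
    symmetrically methylated dyad at most one strand is cleaved, chosen by a
    fair coin.  5hmC is never excised.  Background nicks arrive per base per
    strand with probability ``p_bg``.
    """
    nicks = []
    for unit in _pair_mods(molecule.mods):
        if unit[0][2] == "5hmC":
            continue
        if rng.random() >= params.p_nick:
            continue
        if len(unit) == 2:
            pick = unit[int(rng.integers(2))]
        else:
            pick = unit[0]
        nicks.append((pick[0], pick[1]))
    L = molecule.end - molecule.start
    for strand in "+-":
        n_bg = rng.binomial(L, params.p_bg)
        for pos in rng.integers(molecule.start, molecule.end, size=n_bg):
            nicks.append((int(pos), strand))
    return replace(molecule, nicks=sorted(set(nicks)))


class SimReadSet:
    """Simulated library: a ground-truth placement table plus lazy reads.

    ``truth`` holds one row per retained read pair (positive design) or per
    molecule (negative design, with a ``fate`` column); FASTQ/SAM records are
    materialized on demand from the genome so the object stays light at high
    depth.
    """

    def __init__(self, truth: pd.DataFrame, genome: ReferenceGenome,
                 params: SimParams, library: str):
        self.truth = truth
        self.genome = genome
        self.params = params
        self.library = library

    def __len__(self):
        return int((self.truth["read_id"] != "").sum()) if len(self.truth) else 0

    def read_rows(self) -> pd.DataFrame:
        t = self.truth
        return t[t["read_id"] != ""]

    def fragments(self) -> pd.DataFrame:
        """Surviving molecule intervals (negative/input design)."""
        t = self.read_rows()
        cols = {"contig": t["contig"], "start": t["frag_start"], "end": t["frag_end"]}
        return pd.DataFrame(cols).reset_index(drop=True)

    def iter_read_pairs(self):
        """Yield (name, seq1, seq2); read 1 carries the adaptor prefix tag."""
        tag = self.params.prefix_tag if self.library == "dmn_plus" else ""
        rl = self.params.read_len
        for row in self.read_rows().itertuples(index=False):
            seq = self.genome.sequence(row.contig)
            if self.library == "dmn_plus":
                r1 = seq[row.r1_start:row.r1_end]
                if row.strand == "-":
                    r1 = revcomp(r1)
                    r2_lo = row.piece_start
                    r2_hi = min(row.piece_start + rl, row.piece_end)
                    r2 = seq[r2_lo:r2_hi]
                else:
                    r2_lo = max(row.piece_start, row.piece_end - rl)
                    r2 = revcomp(seq[r2_lo:row.piece_end])
                yield row.read_id, tag + r1, r2
            else:
                r1 = seq[row.frag_start:min(row.frag_start + rl, row.frag_end)]
                r2 = revcomp(seq[max(row.frag_start, row.frag_end - rl):row.frag_end])
                yield row.read_id, r1, r2

    def write_fastq(self, r1_path, r2_path) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for name, s1, s2 in self.iter_read_pairs():
                f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")

    def write_truth(self, path) -> None:
        """Truth placements with 1-based inclusive alignment coordinates."""
        t = self.truth.copy()
        t["align_start_1based"] = t["r1_start"] + 1
        t["align_end_1based"] = t["r1_end"]
        t.to_csv(path, sep="\t", index=False)

    def write_sam(self, path) -> None:
        from . import io as _io

        _io.write_sam(self.read_rows(), self.genome, path)


_PLUS_COLUMNS = ["read_id", "contig", "frag_id", "strand", "r1_start", "r1_end",
                 "piece_start", "piece_end", "nick_pos", "is_background",
                 "frag_start", "frag_end", "fate"]


def _empty_plus_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(str if c in ("read_id", "contig", "strand", "fate")
                                             else bool if c == "is_background" else np.int64))
                         for c in _PLUS_COLUMNS})


def _realize_pairs(units, starts, ends, rng):
    """Vectorized unit-in-fragment realization for one contig.

    Returns (frag_idx, unit_idx) index pairs of realized methylation units.
    """
    anchor, span_end, beta = units["anchor"], units["span_end"], units["beta"]
    lo = np.searchsorted(anchor, starts, side="left")
    hi = np.searchsorted(anchor, ends, side="left")
    counts = hi - lo
    frag_idx = np.repeat(np.arange(len(starts)), counts)
    unit_idx = np.repeat(lo, counts) + _ranges(counts)
    inside = span_end[unit_idx] <= ends[frag_idx]
    frag_idx, unit_idx = frag_idx[inside], unit_idx[inside]
    realized = rng.random(len(unit_idx)) < beta[unit_idx]
    return frag_idx[realized], unit_idx[realized]


def build_dmnplus_library(genome: ReferenceGenome, methylome: Methylome,
                          params: SimParams) -> SimReadSet:
    """Simulate the positive (5mC-enrichment) library.

    Per molecule: fragmentize, realize methylation, nick, cut each strand at
    its nicks, and emit one read pair per nick-derived piece of length at
    least ``min_frag_len``.  Molecules without nicks yield no reads.  The
    same seed reproduces the library byte for byte.
    """
    rng_frag, rng_real, rng_nick, rng_bg = _substreams(params.seed, 4)
    compiled = methylome.compiled()
    frames = []
    frag_offset = 0
    frags = fragmentize(genome, params, rng_frag)
    for contig in genome.names:
        sub = frags[frags["contig"] == contig]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        nfrag = len(starts)
        if nfrag == 0:
            continue

        nick_frag = []
        nick_pos = []
        nick_strand = []
        nick_bg = []
        units = compiled.get(contig)
        if units is not None and len(units["pos1"]):
            f_idx, u_idx = _realize_pairs(units, starts, ends, rng_real)
            not_hmc = ~units["hmc"][u_idx]
            f_idx, u_idx = f_idx[not_hmc], u_idx[not_hmc]
            nicked = rng_nick.random(len(u_idx)) < params.p_nick
            f_idx, u_idx = f_idx[nicked], u_idx[nicked]
            is_dyad = units["pos2"][u_idx] >= 0
            pick_second = np.logical_and(is_dyad, rng_nick.integers(0, 2, len(u_idx)) == 1)
            pos = np.where(pick_second, units["pos2"][u_idx], units["pos1"][u_idx])
            strand = np.where(pick_second, units["strand2"][u_idx], units["strand1"][u_idx])
            nick_frag.append(f_idx)
            nick_pos.append(pos)
            nick_strand.append(strand.astype(np.int8))
            nick_bg.append(np.zeros(len(pos), dtype=bool))

        if params.p_bg > 0:
            lens = ends - starts
            n_bg = rng_bg.binomial(2 * lens, params.p_bg)
            total_bg = int(n_bg.sum())
            if total_bg:
                bf = np.repeat(np.arange(nfrag), n_bg)
                off = rng_bg.random(total_bg)
                bp = starts[bf] + np.floor(off * lens[bf]).astype(np.int64)
                bs = rng_bg.integers(0, 2, total_bg).astype(np.int8)
                nick_frag.append(bf)
                nick_pos.append(bp)
                nick_strand.append(bs)
                nick_bg.append(np.ones(total_bg, dtype=bool))

        if not nick_frag:
            frag_offset += nfrag
            continue
        f = np.concatenate(nick_frag)
        p = np.concatenate(nick_pos)
        s = np.concatenate(nick_strand)
        bg = np.concatenate(nick_bg)

        order = np.lexsort((p, s, f))
        f, p, s, bg = f[order], p[order], s[order], bg[order]
        # collapse coincident nicks on the same molecule/strand
        dup = np.zeros(len(f), dtype=bool)
        if len(f) > 1:
            dup[1:] = (f[1:] == f[:-1]) & (s[1:] == s[:-1]) & (p[1:] == p[:-1])
        f, p, s, bg = f[~dup], p[~dup], s[~dup], bg[~dup]

        fe = ends[f]
        fs = starts[f]
        same_next = np.zeros(len(f), dtype=bool)
        same_prev = np.zeros(len(f), dtype=bool)
        if len(f) > 1:
            adj = (f[1:] == f[:-1]) & (s[1:] == s[:-1])
            same_next[:-1] = adj
            same_prev[1:] = adj
        next_pos = np.empty_like(p)
        next_pos[:-1] = p[1:]
        next_pos[-1] = 0
        prev_pos = np.empty_like(p)
        prev_pos[1:] = p[:-1]
        prev_pos[0] = 0

        plus = s == 0
        piece_start = np.where(plus, p + 1, np.where(same_prev, prev_pos + 1, fs))
        piece_end = np.where(plus, np.where(same_next, next_pos, fe), p)
        length = piece_end - piece_start
        keep = length >= params.min_frag_len

        payload = max(params.read_len - len(params.prefix_tag), 1)
        g = np.minimum(payload, length[keep])
        ps, pe = piece_start[keep], piece_end[keep]
        kplus = plus[keep]
        r1_start = np.where(kplus, ps, pe - g)
        r1_end = np.where(kplus, ps + g, pe)

        frames.append(pd.DataFrame({
            "read_id": "",
            "contig": contig,
            "frag_id": f[keep] + frag_offset,
            "strand": np.where(kplus, "+", "-"),
            "r1_start": r1_start,
            "r1_end": r1_end,
            "piece_start": ps,
            "piece_end": pe,
            "nick_pos": p[keep],
            "is_background": bg[keep],
            "frag_start": fs[keep],
            "frag_end": fe[keep],
            "fate": "amplified_plus",
        }))
        frag_offset += nfrag

    if frames:
        truth = pd.concat(frames, ignore_index=True)
        truth["read_id"] = [f"dmnplus:{params.seed}:{i}" for i in range(len(truth))]
    else:
        truth = _empty_plus_truth()
    return SimReadSet(truth, genome, params, "dmn_plus")


def build_dmnminus_library(genome: ReferenceGenome, methylome: Methylome,
                           params: SimParams, treated: bool = True) -> SimReadSet:
    """Simulate the negative (hypomethylation-enrichment) library.

    Treated: a molecule survives iff it carries zero realized 5mC on either
    strand, except it escapes depletion with probability ``epsilon_escape``;
    survivors inside the size-selection window yield read pairs spanning the
    fragment.  Untreated (input): every molecule passes; only size selection
    applies.
    """
    rng_frag, rng_real, rng_surv = _substreams(params.seed, 4)[:3]
    compiled = methylome.compiled()
    frags = fragmentize(genome, params, rng_frag)
    rows = []
    frag_offset = 0
    for contig in genome.names:
        sub = frags[frags["contig"] == contig]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        nfrag = len(starts)
        if nfrag == 0:
            continue
        has_mc = np.zeros(nfrag, dtype=bool)
        units = compiled.get(contig)
        if units is not None and len(units["pos1"]):
            f_idx, u_idx = _realize_pairs(units, starts, ends, rng_real)
            mc = ~units["hmc"][u_idx]
            np.logical_or.at(has_mc, f_idx[mc], True)
        lo, hi = params.size_select
        lens = ends - starts
        in_size = (lens >= lo) & (lens <= hi)
        if treated:
            escape = rng_surv.random(nfrag) < params.epsilon_escape
            survive = (~has_mc | escape) & in_size
            fate = np.where(survive, "amplified_minus_lib", "dropped")
        else:
            survive = in_size
            fate = np.where(survive, "input", "dropped")
        rows.append(pd.DataFrame({
            "read_id": "",
            "contig": contig,
            "frag_id": np.arange(nfrag) + frag_offset,
            "strand": "+",
            "r1_start": starts,
            "r1_end": ends,
            "frag_start": starts,
            "frag_end": ends,
            "had_5mC": has_mc,
            "fate": fate,
        }))
        frag_offset += nfrag
    if rows:
        truth = pd.concat(rows, ignore_index=True)
        alive = truth["fate"] != "dropped"
        prefix = "dmnminus" if treated else "input"
        ids = np.full(len(truth), "", dtype=object)
        ids[alive.to_numpy()] = [f"{prefix}:{params.seed}:{i}"
                                 for i in range(int(alive.sum()))]
        truth["read_id"] = ids
    else:
        truth = pd.DataFrame(columns=["read_id", "contig", "frag_id", "strand",
                                      "r1_start", "r1_end", "frag_start",
                                      "frag_end", "had_5mC", "fate"])
    return SimReadSet(truth, genome, params, "dmn_minus" if treated else "input")


def build_bisulfite_truth(genome: ReferenceGenome, methylome: Methylome,
                          params: SimParams) -> pd.DataFrame:
    """Bisulfite-style per-site counts: total ~ Poisson(depth), unconverted ~
    Binomial(total, beta).  The methylation ratio is unconverted/total and is
    left missing (NaN) at uncovered sites."""
    rng = _substreams(params.seed, 5)[4]
    table = methylome.beta_table()
    total = rng.poisson(params.depth, size=len(table))
    unconv = rng.binomial(total, table["beta"].to_numpy())
    out = table[["contig", "pos", "strand", "beta"]].copy()
    out["unconverted"] = unconv
    out["total"] = total
    out["ratio"] = np.where(total > 0, unconv / np.maximum(total, 1), np.nan)
    return out
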