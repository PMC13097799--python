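"""Synthetic genomes, methylomes, cohorts and spike-in oligos.

Every generator is a pure function of its arguments and seed, so a rerun is
bitwise identical.  The generators emulate the assay's study material: a
λ-like control genome carrying partially methylated Dcm (CCWGG) dyads, a
CpG-dominated methylome with promoter hypomethylation, paired tumor/healthy
cohorts with planted differentially methylated promoters, and short duplex
oligos with known modified positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    Methylome,
    MethylSite,
    ReferenceGenome,
    RegionSet,
    resolve_regions,
    scan_cpg_dyads,
    scan_dcm_dyads,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class CohortSpec:
    """Design of a paired two-condition cohort with planted DMRs.

    ``effect_beta_delta`` is the mean methylation-level shift in planted
    regions (tumor below healthy in a ``fraction_hypo`` of them, above in the
    rest); ``noise_sd`` is the SD of the truncated-Gaussian per-sample jitter
    on beta.
    """

    n_pairs: int = 6
    n_regions: int = 24
    fraction_hypo: float = 0.5
    effect_beta_delta: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_regions < 1:
            raise ValueError("n_pairs and n_regions must be positive")
        if not 0.0 <= self.fraction_hypo <= 1.0:
            raise ValueError("fraction_hypo must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SpikeInOligo:
    """Short duplex oligo with known modified cytosine positions."""

    name: str
    sequence: str
    mod_positions: tuple  # of (pos, strand, base_mod)


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def gen_genome(n_contigs: int, length: int, gc: float, seed: int,
               n_dcm: int | None = None) -> ReferenceGenome:
    """Pseudo-random genome; optionally enriched to ~``n_dcm`` CCWGG dyads.

    ``n_dcm`` (total across contigs) plants extra CCAGG/CCTGG motifs at
    random non-overlapping positions until the scanned dyad count reaches the
    requested value, mimicking the elevated Dcm density of the λ control.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be strictly inside (0,1), got {gc}")
    if length < 1000:
        raise ValueError("contig length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    contigs = []
    for i in range(n_contigs):
        arr = _rand_seq(rng, length, gc)
        contigs.append((f"contig_{i + 1}", arr))

    if n_dcm is not None:
        per_contig = n_dcm // n_contigs
        genome0 = ReferenceGenome([(n, a.tobytes().decode()) for n, a in contigs])
        have = {}
        for c, p, q in scan_dcm_dyads(genome0):
            have.setdefault(c, []).append(p - 1)
        for name, arr in contigs:
            existing = set(have.get(name, []))
            need = per_contig - len(existing)
            if need <= 0:
                continue
            taken = sorted(existing)
            candidates = rng.permutation(length - 5)
            motifs = np.array([b"CCAGG", b"CCTGG"])
            for pos in candidates:
                if need <= 0:
                    break
                # keep plants >= 5 bp apart from any existing/planted motif
                if any(abs(pos - t) < 5 for t in taken):
                    continue
                motif = motifs[rng.integers(2)]
                arr[pos:pos + 5] = np.frombuffer(motif, dtype="S1")
                taken.append(int(pos))
                need -= 1

    return ReferenceGenome([(n, a.tobytes().decode()) for n, a in contigs])


def gen_lambda_like_methylome(genome: ReferenceGenome, beta_law, seed: int) -> Methylome:
    """Partially methylated Dcm methylome: one beta per CCWGG dyad.

    ``beta_law`` is ``("fixed", b)`` or ``("uniform", lo, hi)``.  Both strand
    cytosines of a dyad share the beta; all non-Dcm cytosines are
    unmethylated (absent from the methylome).
    """
    dyads = scan_dcm_dyads(genome)
    if not dyads:
        raise ValueError("genome contains no Dcm (CCWGG) dyads")
    rng = np.random.default_rng(seed)
    if beta_law[0] == "fixed":
        betas = np.full(len(dyads), float(beta_law[1]))
    elif beta_law[0] == "uniform":
        betas = rng.uniform(float(beta_law[1]), float(beta_law[2]), size=len(dyads))
    else:
        raise ValueError(f"unknown beta law {beta_law!r}")
    me = Methylome()
    for (contig, p, q), b in zip(dyads, betas):
        me.add_dyad(contig, p, q, float(b))
    return me


def gen_tss_methylome(genome: ReferenceGenome, genes: RegionSet, beta_body: float,
                      beta_tss: float, tss_halfwidth: int, seed: int) -> Methylome:
    """CpG methylome with promoter hypomethylation troughs.

    CpG dyads within ``tss_halfwidth`` of a TSS get ``beta_tss``; all other
    CpG dyads get ``beta_body``.  Overlapping windows resolve to the minimum
    beta (hypomethylation wins).
    """
    if beta_tss >= beta_body:
        raise ValueError("beta_tss must be below beta_body for a hypomethylation trough")
    del seed  # deterministic pattern; kept for generator-signature uniformity
    tss_by_contig: dict[str, list[int]] = {}
    for contig, start, end, _name, strand in genes:
        tss = end - 1 if strand == "-" else start
        tss_by_contig.setdefault(contig, []).append(tss)
    me = Methylome()
    for contig, p, q in scan_cpg_dyads(genome):
        beta = beta_body
        for tss in tss_by_contig.get(contig, ()):
            if abs(p - tss) <= tss_halfwidth:
                beta = min(beta, beta_tss)
        me.add_dyad(contig, p, q, beta)
    return me


def gen_cohort(genome: ReferenceGenome, genes: RegionSet, spec: CohortSpec,
               beta_body: float = 0.75, beta_promoter: float = 0.25,
               promoter_flank: int = 2000, n_open: int = 0,
               open_len: int = 2000, beta_open: float = 0.02):
    """Paired tumor/healthy methylomes with planted promoter DMRs.

    Healthy baseline: CpG dyads at ``beta_body`` outside promoters and
    ``beta_promoter`` inside TSS-upstream windows of width
    ``promoter_flank``.  ``spec.n_regions`` promoters are planted as DMRs:
    tumor beta shifts down by ``effect_beta_delta`` (floored at 0) in a
    ``fraction_hypo`` share of them and up (capped at 1) in the rest.  Each
    sample adds one truncated-Gaussian jitter per promoter region and
    per-site jitter elsewhere.

    ``n_open`` additionally plants condition-invariant constitutively
    hypomethylated windows (length ``open_len``, beta ``beta_open``) in
    non-promoter space.  They emulate the genome-wide unmethylated
    background that dominates a real depletion library's mapped mass and
    keep total-count normalization stable when the planted effects are not
    balanced.

    Returns ``(pairs, truth)`` where pairs is a list of ``(tumor, healthy)``
    Methylomes and truth a DataFrame of the planted regions.
    """
    promoters = resolve_regions(genome, genes, "tss_upstream", promoter_flank)
    if spec.n_regions > len(promoters):
        raise ValueError(
            f"n_regions={spec.n_regions} exceeds available promoters ({len(promoters)})")
    rng = np.random.default_rng(spec.seed)

    cpgs = scan_cpg_dyads(genome)
    n_cpg = len(cpgs)
    base = np.full(n_cpg, beta_body)
    region_of = np.full(n_cpg, -1)  # promoter index per CpG, -1 = body
    for ridx, (contig, start, end, _n, _s) in enumerate(promoters):
        for i, (c, p, _q) in enumerate(cpgs):
            if c == contig and start <= p < end:
                base[i] = beta_promoter
                region_of[i] = ridx

    if n_open:
        # invariant open windows on a tiling grid, avoiding promoters
        busy = {(c, s // open_len) for i, (c, s, _e) in enumerate(cpgs)
                if region_of[i] >= 0}
        free = [(contig, t) for contig in genome.names
                for t in range(genome.length(contig) // open_len)
                if (contig, t) not in busy]
        if n_open > len(free):
            raise ValueError(f"n_open={n_open} exceeds free {open_len} bp tiles "
                             f"({len(free)})")
        pick = rng.choice(len(free), size=n_open, replace=False)
        open_tiles = {free[i] for i in pick}
        for i, (c, p, _q) in enumerate(cpgs):
            if region_of[i] < 0 and (c, p // open_len) in open_tiles:
                base[i] = beta_open

    chosen = np.sort(rng.choice(len(promoters), size=spec.n_regions, replace=False))
    n_hypo = int(round(spec.fraction_hypo * spec.n_regions))
    hypo_set = set(chosen[rng.permutation(spec.n_regions)[:n_hypo]].tolist())

    effect = np.zeros(len(promoters))
    direction = {}
    for ridx in chosen:
        if ridx in hypo_set:
            effect[ridx] = -spec.effect_beta_delta
            direction[ridx] = "hypo"
        else:
            effect[ridx] = +spec.effect_beta_delta
            direction[ridx] = "hyper"

    tumor_base = base.copy()
    mask = region_of >= 0
    tumor_base[mask] = np.clip(base[mask] + effect[region_of[mask]], 0.0, 1.0)

    def _sample(base_beta):
        beta = base_beta.copy()
        region_jitter = rng.normal(0.0, spec.noise_sd, size=len(promoters))
        site_jitter = rng.normal(0.0, spec.noise_sd, size=n_cpg)
        jit = np.where(mask, region_jitter[np.clip(region_of, 0, None)], site_jitter)
        beta = np.clip(beta + jit, 0.0, 1.0)
        me = Methylome()
        for (contig, p, q), b in zip(cpgs, beta):
            me.add_dyad(contig, p, q, float(b))
        return me

    pairs = [(_sample(tumor_base), _sample(base)) for _ in range(spec.n_pairs)]

    rows = []
    for ridx in chosen:
        contig, start, end, name, strand = promoters.intervals[ridx]
        rows.append((name, contig, start, end, strand, direction[ridx],
                     float(effect[ridx])))
    truth = pd.DataFrame(rows, columns=["region", "contig", "start", "end",
                                        "strand", "direction", "beta_delta"])
    return pairs, truth


def gen_spikeins(seed: int) -> list[SpikeInOligo]:
    """Duplex control oligos with known 5mC/5hmC positions (synthetic stand-ins).

    Emits an 82 bp oligo with one central CpG 5mC, a sequence-identical 82 bp
    oligo carrying 5hmC at the same position, and 164/200 bp oligos with two
    and three known 5mC sites.
    """
    rng = np.random.default_rng(seed)

    def _with_cpgs(length: int, cpg_at: list[int]) -> str:
        arr = _rand_seq(rng, length, 0.5)
        # strip accidental CpGs so the designed ones are the only mod sites
        s = arr.tobytes().decode()
        s = list(s.replace("CG", "CA"))
        for p in cpg_at:
            s[p], s[p + 1] = "C", "G"
        return "".join(s)

    seq82 = _with_cpgs(82, [40])
    oligos = [
        SpikeInOligo("oligo82_5mC", seq82, ((40, "+", "5mC"), (41, "-", "5mC"))),
        SpikeInOligo("oligo82_5hmC", seq82, ((40, "+", "5hmC"), (41, "-", "5hmC"))),
        SpikeInOligo("oligo164_5mC", _with_cpgs(164, [50, 110]),
                     ((50, "+", "5mC"), (51, "-", "5mC"),
                      (110, "+", "5mC"), (111, "-", "5mC"))),
        SpikeInOligo("oligo200_5mC", _with_cpgs(200, [40, 100, 160]),
                     ((40, "+", "5mC"), (41, "-", "5mC"),
                      (100, "+", "5mC"), (101, "-", "5mC"),
                      (160, "+", "5mC"), (161, "-", "5mC"))),
    ]
    return oligos


def spikein_methylome(oligos: list[SpikeInOligo], beta: float = 1.0) -> tuple[ReferenceGenome, Methylome]:
    """Bundle spike-in oligos into a genome + fully specified methylome."""
    genome = ReferenceGenome([(o.name, o.sequence) for o in oligos])
    me = Methylome()
    for o in oligos:
        plus = [(p, m) for p, s, m in o.mod_positions if s == "+"]
        minus = {p: m for p, s, m in o.mod_positions if s == "-"}
        for p, mod in plus:
            if p + 1 in minus:
                me.add_dyad(o.name, p, p + 1, beta, mod)
                del minus[p + 1]
            else:
                me.add_site(MethylSite(o.name, p, "+", beta, mod))
        for q, mod in minus.items():
            me.add_site(MethylSite(o.name, q, "-", beta, mod))
    return genome, me


def gen_genes(genome: ReferenceGenome, n_genes: int, gene_len: int, seed: int,
              min_gap: int = 500) -> RegionSet:
    """Non-overlapping stranded gene anchors spread over the genome."""
    rng = np.random.default_rng(seed)
    intervals = []
    gidx = 0
    names = genome.names
    per = [n_genes // len(names) + (1 if i < n_genes % len(names) else 0)
           for i in range(len(names))]
    for name, count in zip(names, per):
        clen = genome.length(name)
        usable = clen - gene_len - min_gap
        if usable <= 0 or count == 0:
            continue
        slots = np.sort(rng.choice(usable // (gene_len + min_gap), size=min(
            count, usable // (gene_len + min_gap)), replace=False))
        for s in slots:
            start = int(s) * (gene_len + min_gap) + min_gap
            strand = "+" if rng.integers(2) == 0 else "-"
            gidx += 1
            intervals.append((name, start, start + gene_len, f"gene_{gidx}", strand))
    return RegionSet(intervals)
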