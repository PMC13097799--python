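"""Canned study conditions used by the examples, tests and acceptance runs.

Each preset fixes the synthetic inputs (genome, methylome, gene models) and
simulation parameters of one benchmark scenario; callers supply only seeds.
The sizes are chosen so each scenario runs in minutes on one CPU while
keeping per-site/per-region counts in the regime the corresponding benchmark
operates in.
"""

from __future__ import annotations

from .genome import Methylome, ReferenceGenome, RegionSet, scan_cpg_dyads
from .simulate import SimParams
from .synthetic import CohortSpec, gen_cohort, gen_genes, gen_genome, gen_lambda_like_methylome, gen_tss_methylome

LAMBDA_GENOME_LEN = 50_000
LAMBDA_N_DCM = 600
LAMBDA_N_FRAGMENTS = 500_000


def lambda_like(genome_seed: int = 7) -> tuple[ReferenceGenome, Methylome]:
    """50 kb λ-like control: ~600 Dcm dyads, dyad beta ~ U(0.05, 0.95)."""
    genome = gen_genome(1, LAMBDA_GENOME_LEN, gc=0.5, seed=genome_seed,
                        n_dcm=LAMBDA_N_DCM)
    methylome = gen_lambda_like_methylome(genome, ("uniform", 0.05, 0.95),
                                          seed=genome_seed + 1)
    return genome, methylome


def lambda_params(seed: int) -> SimParams:
    """High-depth positive-design parameters: ~500k fragments over 50 kb."""
    depth = LAMBDA_N_FRAGMENTS * 350.0 / LAMBDA_GENOME_LEN  # => ~500k fragments
    return SimParams(depth=depth, p_nick=0.5, p_bg=1e-6, seed=seed)


def cpg_only(genome_seed: int = 11, beta: float = 0.8,
             length: int = 1_000_000) -> tuple[ReferenceGenome, Methylome]:
    """1 Mb genome methylated at CpG dyads only (beta 0.8, nothing else)."""
    genome = gen_genome(1, length, gc=0.5, seed=genome_seed)
    methylome = Methylome()
    for contig, p, q in scan_cpg_dyads(genome):
        methylome.add_dyad(contig, p, q, beta)
    return genome, methylome


def cpg_only_params(seed: int) -> SimParams:
    """Depth giving roughly 20 filtered read starts per methylated site."""
    return SimParams(depth=150.0, p_nick=0.5, p_bg=1e-6, seed=seed)


def tss_trough(genome_seed: int = 21):
    """Promoter-hypomethylation scenario for the depletion design.

    300 kb genome, 30 genes; CpG beta 0.8 in gene bodies and 0.02 within
    +/-1 kb of each TSS.  Returns (genome, genes, methylome).
    """
    genome = gen_genome(1, 300_000, gc=0.5, seed=genome_seed)
    genes = gen_genes(genome, n_genes=30, gene_len=4000, seed=genome_seed + 1,
                      min_gap=4500)
    methylome = gen_tss_methylome(genome, genes, beta_body=0.8, beta_tss=0.02,
                                  tss_halfwidth=1000, seed=genome_seed + 2)
    return genome, genes, methylome


def tss_trough_params(seed: int, depth: float = 30.0) -> SimParams:
    return SimParams(depth=depth, frag_len_mean=350, frag_len_sd=70,
                     size_select=(100, 1000), seed=seed)


def crc_cohort(genome_seed: int = 31, cohort_seed: int = 32):
    """Paired tumor/healthy cohort with planted promoter DMRs (low noise).

    600 kb genome at GC 0.4 (moderate CpG density), 12 genes, 6 pairs,
    6 planted DMRs (half hypo, half hyper), beta shift 0.5, jitter SD 0.01,
    plus 150 condition-invariant constitutively unmethylated background
    windows so total-count normalization is stable against the planted
    effects (as genome-wide mapped mass is in a real library).
    Returns (genome, genes, pairs, truth, spec).
    """
    genome = gen_genome(1, 600_000, gc=0.4, seed=genome_seed)
    genes = gen_genes(genome, n_genes=12, gene_len=3000, seed=genome_seed + 1,
                      min_gap=4200)  # gap wide enough that promoter windows never overlap
    spec = CohortSpec(n_pairs=6, n_regions=6, fraction_hypo=0.5,
                      effect_beta_delta=0.5, noise_sd=0.01, seed=cohort_seed)
    pairs, truth = gen_cohort(genome, genes, spec, beta_body=0.75,
                              beta_promoter=0.25, promoter_flank=2000,
                              n_open=150, open_len=2000, beta_open=0.02)
    return genome, genes, pairs, truth, spec


def cfDNA_params(seed: int, depth: float = 100.0) -> SimParams:
    """cfDNA-like short-fragment depletion-design parameters."""
    return SimParams(depth=depth, frag_len_mean=150, frag_len_sd=30,
                     min_frag_len=30, size_select=(100, 250), seed=seed)
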