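import numpy as np
import pandas as pd
import pytest

import dmnseq as d
from dmnseq import presets


@pytest.fixture(scope="session")
def small_genome():
    return d.gen_genome(1, 5000, 0.5, seed=101)


@pytest.fixture(scope="session")
def lambda_scenario():
    """λ-like control genome + partially methylated Dcm methylome."""
    genome, methylome = presets.lambda_like(7)
    return genome, methylome


@pytest.fixture(scope="session")
def lambda_replicates(lambda_scenario):
    """Two independently seeded high-depth positive-design replicates."""
    genome, methylome = lambda_scenario
    lib_a = d.build_dmnplus_library(genome, methylome, presets.lambda_params(1))
    lib_b = d.build_dmnplus_library(genome, methylome, presets.lambda_params(2))
    sig_a = d.extract_start_signals(lib_a.truth, offset=1)
    sig_b = d.extract_start_signals(lib_b.truth, offset=1)
    return lib_a, lib_b, sig_a, sig_b


@pytest.fixture(scope="session")
def cohort_scenario():
    """Paired tumor/healthy cohort with planted promoter DMRs."""
    return presets.crc_cohort(31, 32)


@pytest.fixture(scope="session")
def cohort_counts(cohort_scenario):
    """Promoter CPM matrices for the tumor and healthy groups."""
    from dmnseq.genome import resolve_regions
    from dmnseq.regions import count_regions

    genome, genes, pairs, truth, _spec = cohort_scenario
    promoters = resolve_regions(genome, genes, "tss_upstream", 2000)

    def _counts(methylome, seed):
        lib = d.build_dmnminus_library(genome, methylome,
                                       presets.cfDNA_params(seed), treated=True)
        return count_regions(lib.fragments(), promoters).set_index("region")["cpm"]

    tumor = pd.DataFrame({f"t{i}": _counts(t, 100 + i)
                          for i, (t, _h) in enumerate(pairs)})
    healthy = pd.DataFrame({f"h{i}": _counts(h, 200 + i)
                            for i, (_t, h) in enumerate(pairs)})
    return tumor, healthy, truth, promoters


@pytest.fixture(scope="session")
def graded_beta_scenario():
    """Genome whose CpG beta rises linearly along ten 10 kb regions."""
    from dmnseq.genome import RegionSet, scan_cpg_dyads

    genome = d.gen_genome(1, 100_000, 0.4, seed=51)
    betas = np.linspace(0.0, 0.9, 10)
    regions = RegionSet([("contig_1", i * 10_000, (i + 1) * 10_000, f"r{i}", "+")
                         for i in range(10)])
    methylome = d.Methylome()
    for contig, p, q in scan_cpg_dyads(genome):
        methylome.add_dyad(contig, p, q, float(betas[min(p // 10_000, 9)]))
    return genome, methylome, regions, betas
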