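"""Single-base 5mC calling from read 5' starts (positive-design analysis).

The per-site statistic is the *enrichment intensity*: the number of filtered
read-1 5' ends assigned to a genomic site after the strand-aware offset
correction that maps a piece's 5' terminus back to the excised cytosine.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Methylome, ReferenceGenome, classify_context, revcomp

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["contig", "pos", "strand", "intensity"]


def prefix_filter(read1_seq: str, k: int = 3, tag_base: str = "A") -> tuple[bool, int]:
    """Keep a read only if its first ``k`` bases are all ``tag_base``.

    Returns ``(passed, payload_offset)``; the payload offset is exactly ``k``
    (the simulator prepends exactly ``k`` tag bases, so a genomic base that
    happens to repeat the tag is never trimmed).  Reads shorter than ``k``
    fail.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(read1_seq) < k:
        return False, 0
    passed = read1_seq[:k] == tag_base * k
    return passed, (k if passed else 0)


def extract_start_signals(placements, offset: int = 1, dedup: bool = False) -> pd.DataFrame:
    """Per-(site, strand) counts of read 5' starts.

    ``placements`` is a truth/alignment table with columns ``contig``,
    ``r1_start``, ``r1_end`` (0-based half-open) and ``strand``, or a path to
    a SAM file.  For a plus-strand alignment the 5' position is the leftmost
    aligned base and the site is ``5'pos - offset``; on the minus strand the
    5' position is the rightmost aligned base and the site is
    ``5'pos + offset``.  ``dedup`` collapses identical (start, end, strand)
    alignments to one before counting.
    """
    if offset not in (0, 1):
        raise ValueError("offset must be 0 or 1")
    if not isinstance(placements, pd.DataFrame):
        from . import io as _io

        placements = _io.read_sam_starts(placements)
    df = placements
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        log.warning("dropping %d placements without a usable strand", int(bad.sum()))
        df = df[~bad]
    if dedup:
        df = df.drop_duplicates(subset=["contig", "r1_start", "r1_end", "strand"])
    plus = df["strand"].to_numpy() == "+"
    fivep = np.where(plus, df["r1_start"].to_numpy(), df["r1_end"].to_numpy() - 1)
    site = np.where(plus, fivep - offset, fivep + offset)
    out = (
        pd.DataFrame({"contig": df["contig"].to_numpy(), "pos": site,
                      "strand": df["strand"].to_numpy()})
        .groupby(["contig", "pos", "strand"], as_index=False)
        .size()
        .rename(columns={"size": "intensity"})
        .sort_values(["contig", "pos", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    return out[SIGNAL_COLUMNS]


def call_sites(signals: pd.DataFrame, genome: ReferenceGenome,
               min_intensity: int = 5) -> pd.DataFrame:
    """Threshold signals and annotate cytosine context.

    Sites whose position is not a C on the stated strand (background nicks)
    get context ``non-C``.  Output is sorted by (contig, pos, strand) and
    stable across reruns.
    """
    if min_intensity < 1:
        raise ValueError("min_intensity must be >= 1")
    kept = signals[signals["intensity"] >= min_intensity].copy()
    contexts = []
    for row in kept.itertuples(index=False):
        if not (0 <= row.pos < genome.length(row.contig)) or \
                genome.base_at(row.contig, int(row.pos), row.strand) != "C":
            contexts.append("non-C")
        else:
            contexts.append(classify_context(genome, row.contig, int(row.pos), row.strand))
    kept["context"] = contexts
    return kept.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(drop=True)


def annotate_truth_beta(called: pd.DataFrame, methylome: Methylome) -> pd.DataFrame:
    """Left-join the methylome's per-site beta onto called sites."""
    truth = methylome.beta_table()[["contig", "pos", "strand", "beta"]]
    return called.merge(truth, on=["contig", "pos", "strand"], how="left") \
                 .rename(columns={"beta": "truth_beta"})


def intensity_vs_beta(called: pd.DataFrame, methylome: Methylome):
    """Pair per-site intensities with true methylation levels.

    Returns ``(table, pearson_r)`` over the sites present in both; raises if
    fewer than 3 sites overlap or either variable is constant.
    """
    truth = methylome.beta_table()[["contig", "pos", "strand", "beta"]]
    table = called.merge(truth, on=["contig", "pos", "strand"], how="inner")
    if len(table) < 3:
        raise ValueError(f"only {len(table)} overlapping sites; need >= 3")
    x = table["beta"].to_numpy(dtype=float)
    y = table["intensity"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in beta or intensity")
    r = float(stats.pearsonr(x, y).statistic)
    return table, r


def replicate_correlation(signals_a: pd.DataFrame, signals_b: pd.DataFrame,
                          mode: str = "union") -> float:
    """Pearson r of per-site intensities between two replicates.

    ``union`` (default) imputes 0 for a site absent from one replicate;
    ``intersection`` keeps only shared sites.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    how = "outer" if mode == "union" else "inner"
    merged = signals_a.merge(signals_b, on=["contig", "pos", "strand"],
                             how=how, suffixes=("_a", "_b"))
    merged = merged.fillna({"intensity_a": 0, "intensity_b": 0})
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} joined sites; need >= 3")
    x = merged["intensity_a"].to_numpy(dtype=float)
    y = merged["intensity_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a replicate has constant intensities")
    return float(stats.pearsonr(x, y).statistic)


def pfm_around_sites(genome: ReferenceGenome, called: pd.DataFrame, flank: int = 5):
    """Position frequency matrix centred on called cytosines.

    Minus-strand sites are reverse-complemented before accumulation so the
    centre column is always the called C read 5'->3' on its own strand.
    Returns ``(pfm, n_skipped)``; columns sum to 1; sites within ``flank`` of
    a contig edge are skipped.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    skipped = 0
    for row in called.itertuples(index=False):
        seq = genome.sequence(row.contig)
        lo, hi = row.pos - flank, row.pos + flank + 1
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        window = seq[lo:hi]
        if row.strand == "-":
            window = revcomp(window)
        for j, b in enumerate(window):
            if b in base_idx:
                counts[base_idx[b], j] += 1
    used = counts.sum(axis=0)
    if used.max() == 0:
        raise ValueError("no usable sites for the PFM")
    pfm = counts / np.maximum(used, 1)
    cols = list(range(-flank, flank + 1))
    return pd.DataFrame(pfm, index=list("ACGT"), columns=cols), skipped
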