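"""Window counting and hypomethylation-enrichment analysis (negative design).

Fragment counts per region are depth-normalized to CPM; the per-region
hypomethylation enrichment score is log2((treated_cpm + c)/(input_cpm + c)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genome import ReferenceGenome, RegionSet

REGION_COLUMNS = ["region", "contig", "start", "end", "raw", "cpm"]


def count_regions(fragments: pd.DataFrame, regions: RegionSet,
                  overlap_rule: str = "any_overlap") -> pd.DataFrame:
    """Count fragments per region and normalize to CPM.

    ``any_overlap`` counts a fragment once in every region it touches (so a
    fragment straddling two regions contributes to both); ``midpoint``
    assigns each fragment to at most the regions containing its midpoint.
    CPM uses the total mapped fragment count as denominator.
    """
    if overlap_rule not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    total = len(fragments)
    if total == 0:
        raise ValueError("zero mapped fragments")
    rows = []
    by_contig = {}
    for contig, grp in fragments.groupby("contig"):
        s = np.sort(grp["start"].to_numpy())
        e = np.sort(grp["end"].to_numpy())
        mid = np.sort(((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2))
        by_contig[contig] = (s, e, mid)
    for contig, start, end, name, _strand in regions:
        if contig not in by_contig:
            raw = 0
        else:
            s, e, mid = by_contig[contig]
            if overlap_rule == "any_overlap":
                # overlap iff frag.start < region.end and frag.end > region.start
                raw = int(np.searchsorted(s, end, side="left")
                          - np.searchsorted(e, start, side="right"))
            else:
                raw = int(np.searchsorted(mid, end, side="left")
                          - np.searchsorted(mid, start, side="left"))
        rows.append((name, contig, start, end, raw))
    out = pd.DataFrame(rows, columns=["region", "contig", "start", "end", "raw"])
    out["cpm"] = out["raw"] * 1e6 / total
    return out


def enrichment_score(treated: pd.DataFrame, input_: pd.DataFrame,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-region log2((treated_cpm + c)/(input_cpm + c)); c in CPM units."""
    if not treated["region"].equals(input_["region"]):
        raise ValueError("treated and input region sets differ")
    out = treated.copy()
    out["input_cpm"] = input_["cpm"].to_numpy()
    out["enrich"] = np.log2((out["cpm"] + pseudocount) /
                            (out["input_cpm"] + pseudocount))
    return out


def coverage_arrays(fragments: pd.DataFrame, genome: ReferenceGenome) -> dict[str, np.ndarray]:
    """Per-contig per-base fragment coverage."""
    cov = {name: np.zeros(genome.length(name) + 1, dtype=np.int64)
           for name in genome.names}
    for contig, grp in fragments.groupby("contig"):
        if contig not in cov:
            continue
        np.add.at(cov[contig], grp["start"].to_numpy(), 1)
        np.add.at(cov[contig], grp["end"].to_numpy(), -1)
    return {name: np.cumsum(c)[:-1] for name, c in cov.items()}


@dataclass
class MetageneProfile:
    """Mean normalized coverage in bins around oriented anchors."""

    bins: np.ndarray
    anchor: str
    flank: int
    n_bins: int
    n_anchors: int


def metagene(fragments: pd.DataFrame, genome: ReferenceGenome, genes: RegionSet,
             flank: int, n_bins: int, anchor: str = "tss") -> MetageneProfile:
    """Strand-oriented average coverage profile around TSS or TES anchors.

    Coverage over ``[anchor - flank, anchor + flank)`` is averaged per bin,
    minus-strand genes are mirrored, and the profile is normalized to mean 1.
    Anchors whose window leaves the contig are skipped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if anchor not in ("tss", "tes"):
        raise ValueError("anchor must be 'tss' or 'tes'")
    width = 2 * flank
    if width % n_bins:
        raise ValueError(f"2*flank ({width}) must be divisible by n_bins ({n_bins})")
    bw = width // n_bins
    cov = coverage_arrays(fragments, genome)
    acc = np.zeros(n_bins, dtype=float)
    used = 0
    for contig, start, end, _name, strand in genes:
        if contig not in cov:
            continue
        if anchor == "tss":
            a = end - 1 if strand == "-" else start
        else:
            a = start if strand == "-" else end - 1
        lo, hi = a - flank, a + flank
        if lo < 0 or hi > genome.length(contig):
            continue
        window = cov[contig][lo:hi].astype(float)
        if strand == "-":
            window = window[::-1]
        acc += window.reshape(n_bins, bw).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("no usable anchors")
    prof = acc / used
    mean = prof.mean()
    if mean > 0:
        prof = prof / mean
    return MetageneProfile(prof, anchor, flank, n_bins, used)


def sliding_window_correlation(fragments_a: pd.DataFrame, fragments_b: pd.DataFrame,
                               genome: ReferenceGenome, window: int = 2000,
                               min_depth: int = 5, step: int | None = None) -> float:
    """Pearson r of mean windowed coverage between two samples.

    The genome is tiled into windows of the stated size (step defaults to the
    window, i.e. non-overlapping tiles).  Within each window only positions
    with depth >= ``min_depth`` in *both* samples contribute; windows with no
    qualifying position in either sample are excluded entirely.
    """
    step = step or window
    cov_a = coverage_arrays(fragments_a, genome)
    cov_b = coverage_arrays(fragments_b, genome)
    xs, ys = [], []
    for contig in genome.names:
        a, b = cov_a[contig], cov_b[contig]
        ok = (a >= min_depth) & (b >= min_depth)
        for lo in range(0, genome.length(contig) - window + 1, step):
            sel = ok[lo:lo + window]
            if not sel.any():
                continue
            xs.append(a[lo:lo + window][sel].mean())
            ys.append(b[lo:lo + window][sel].mean())
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} qualifying windows; need >= 3")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant windowed coverage")
    return float(stats.pearsonr(x, y).statistic)


def cluster_samples(matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering on (1 - Pearson) distance.

    ``matrix`` is samples x regions (CPM profiles).  Returns the SciPy
    linkage matrix; row order of ``matrix`` fixes leaf indices, and SciPy's
    lowest-index-first tie-breaking makes the result deterministic.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples to cluster")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1)
    for sample, sd in zip(matrix.index, sds):
        if sd == 0:
            raise ValueError(f"sample {sample!r} has a constant profile; "
                             "its correlations are undefined")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def top_split(link, labels: list[str]) -> tuple[set, set]:
    """Leaf labels of the two subtrees below the final merge."""
    from scipy.cluster.hierarchy import fcluster

    assign = fcluster(link, t=2, criterion="maxclust")
    one = {l for l, a in zip(labels, assign) if a == 1}
    two = {l for l, a in zip(labels, assign) if a == 2}
    return one, two
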