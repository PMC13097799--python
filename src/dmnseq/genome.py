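"""Reference sequences, per-site methylomes, and cytosine motif/context logic.

Coordinates are 0-based half-open everywhere inside the package; user-facing
tables are written 1-based.  A cytosine "site" always lives on a strand: on the
minus strand the reference (plus-strand) base at the site is ``G``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_MODS = ("5mC", "5hmC")
CONTEXTS = ("CpG", "CHG", "CHH")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N alphabet, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """Ordered collection of named contigs over the {A,C,G,T,N} alphabet.

    Parameters
    ----------
    contigs
        Iterable of ``(name, sequence)`` pairs.  Names must be unique and
        sequences non-empty; sequences are upper-cased on ingest.
    """

    def __init__(self, contigs: Iterable[tuple[str, str]]):
        self._contigs: dict[str, str] = {}
        for name, seq in contigs:
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            if name in self._contigs:
                raise ValueError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} contains invalid characters {sorted(bad)}")
            self._contigs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    def sequence(self, name: str) -> str:
        return self._contigs[name]

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._contigs.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceGenome) and self._contigs == other._contigs

    def base_at(self, contig: str, pos: int, strand: str) -> str:
        """Base at ``pos`` read on the given strand."""
        b = self._contigs[contig][pos]
        return b if strand == "+" else b.translate(_COMPLEMENT)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        from . import io as _io

        return _io.read_fasta(path)

    def to_fasta(self, path) -> None:
        from . import io as _io

        _io.write_fasta(self, path)


@dataclass(frozen=True)
class MethylSite:
    """A modified cytosine with its population methylation level beta."""

    contig: str
    pos: int
    strand: str
    beta: float
    base_mod: str = "5mC"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if self.base_mod not in VALID_MODS:
            raise ValueError(f"base_mod must be one of {VALID_MODS}, got {self.base_mod!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


class Methylome:
    """Mapping of (contig, pos, strand) to :class:`MethylSite`.

    Symmetric dyads (the two strand cytosines of a CpG, or the two internal
    Cs of a Dcm CCWGG motif) may be registered as pairs; paired sites share
    one beta and the simulator realizes them jointly per molecule.
    """

    def __init__(self):
        self.sites: dict[tuple[str, int, str], MethylSite] = {}
        # each entry: (plus_site_key, minus_site_key)
        self.dyads: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = []
        self._in_dyad: set[tuple[str, int, str]] = set()

    def __len__(self) -> int:
        return len(self.sites)

    def add_site(self, site: MethylSite) -> None:
        if site.key in self.sites:
            raise ValueError(f"duplicate methylation site {site.key}")
        self.sites[site.key] = site

    def add_dyad(self, contig: str, plus_pos: int, minus_pos: int, beta: float,
                 base_mod: str = "5mC") -> None:
        """Register a symmetrically methylated dyad sharing one beta."""
        if not plus_pos < minus_pos:
            raise ValueError("dyad plus-strand position must precede the minus-strand one")
        a = MethylSite(contig, plus_pos, "+", beta, base_mod)
        b = MethylSite(contig, minus_pos, "-", beta, base_mod)
        self.add_site(a)
        self.add_site(b)
        self.dyads.append((a.key, b.key))
        self._in_dyad.update((a.key, b.key))

    def in_dyad(self, key: tuple[str, int, str]) -> bool:
        return key in self._in_dyad

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check every site is a C on its stated strand of the reference."""
        for (contig, pos, strand), site in self.sites.items():
            if contig not in genome:
                raise ValueError(f"site contig {contig!r} absent from genome")
            if not 0 <= pos < genome.length(contig):
                raise ValueError(f"site {site.key} outside contig bounds")
            if genome.base_at(contig, pos, strand) != "C":
                raise ValueError(f"reference base at {site.key} is not C on that strand")
        for a, b in self.dyads:
            if abs(self.sites[a].beta - self.sites[b].beta) > 1e-12:
                raise ValueError(f"dyad {a}/{b} betas differ")

    def singles(self) -> list[MethylSite]:
        """Sites not belonging to any dyad."""
        return [s for k, s in self.sites.items() if k not in self._in_dyad]

    def compiled(self):
        """Per-contig arrays of methylation *units* for the vectorized simulator.

        A unit is either a dyad (two strand positions, one beta) or a lone
        site.  Returns ``{contig: dict(pos1, strand1, pos2, strand2, beta,
        hmc, anchor, span_end)}`` with ``pos2 = -1`` for lone sites, sorted
        by ``anchor`` (the leftmost position of the unit).
        """
        import numpy as np

        per: dict[str, dict[str, list]] = {}

        def _bucket(contig):
            return per.setdefault(
                contig,
                {k: [] for k in ("pos1", "strand1", "pos2", "strand2", "beta", "hmc")},
            )

        for a, b in self.dyads:
            sa, sb = self.sites[a], self.sites[b]
            u = _bucket(sa.contig)
            u["pos1"].append(sa.pos)
            u["strand1"].append(0)
            u["pos2"].append(sb.pos)
            u["strand2"].append(1)
            u["beta"].append(sa.beta)
            u["hmc"].append(sa.base_mod == "5hmC")
        for s in self.singles():
            u = _bucket(s.contig)
            u["pos1"].append(s.pos)
            u["strand1"].append(0 if s.strand == "+" else 1)
            u["pos2"].append(-1)
            u["strand2"].append(-1)
            u["beta"].append(s.beta)
            u["hmc"].append(s.base_mod == "5hmC")

        out = {}
        for contig, u in per.items():
            pos1 = np.asarray(u["pos1"], dtype=np.int64)
            pos2 = np.asarray(u["pos2"], dtype=np.int64)
            anchor = np.where(pos2 >= 0, np.minimum(pos1, pos2), pos1)
            span_end = np.maximum(pos1, pos2) + 1
            order = np.argsort(anchor, kind="stable")
            out[contig] = {
                "pos1": pos1[order],
                "strand1": np.asarray(u["strand1"], dtype=np.int8)[order],
                "pos2": pos2[order],
                "strand2": np.asarray(u["strand2"], dtype=np.int8)[order],
                "beta": np.asarray(u["beta"], dtype=np.float64)[order],
                "hmc": np.asarray(u["hmc"], dtype=bool)[order],
                "anchor": anchor[order],
                "span_end": span_end[order],
            }
        return out

    def beta_table(self):
        """Long-format (contig, pos, strand, beta, base_mod) DataFrame."""
        import pandas as pd

        rows = [
            (s.contig, s.pos, s.strand, s.beta, s.base_mod)
            for s in sorted(self.sites.values(), key=lambda s: (s.contig, s.pos, s.strand))
        ]
        return pd.DataFrame(rows, columns=["contig", "pos", "strand", "beta", "base_mod"])


@dataclass
class RegionSet:
    """Named, stranded genomic intervals (0-based half-open)."""

    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    # each: (contig, start, end, name, strand)

    def __post_init__(self):
        for contig, start, end, name, strand in self.intervals:
            if start >= end:
                raise ValueError(f"region {name!r}: start {start} >= end {end}")
            if strand not in "+-.":
                raise ValueError(f"region {name!r}: bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        from . import io as _io

        return _io.read_bed(path)

    def to_bed(self, path) -> None:
        from . import io as _io

        _io.write_bed(self, path)


def classify_context(genome: ReferenceGenome, contig: str, pos: int, strand: str) -> str:
    """Cytosine context (CpG / CHG / CHH) from the two bases 3' of the C.

    The two downstream bases are read along the site's own strand, so on the
    minus strand they are the complements of the reference bases at ``pos-1``
    and ``pos-2``.  Bases that fall off the contig end, or are ``N``, are
    treated as H (the conservative non-G fallback), so a C with no readable
    3' neighbours classifies as CHH.
    """
    seq = genome.sequence(contig)
    if genome.base_at(contig, pos, strand) != "C":
        raise ValueError(f"base at {contig}:{pos}({strand}) is not C on that strand")
    if strand == "+":
        b1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        b2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    else:
        b1 = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else "N"
        b2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else "N"
    if b1 == "G":
        return "CpG"
    if b2 == "G":
        return "CHG"
    return "CHH"


_DCM_RE = re.compile(r"(?=CC[AT]GG)")


def scan_dcm_dyads(genome: ReferenceGenome) -> list[tuple[str, int, int]]:
    """All Dcm (CCWGG) dyads as ``(contig, plus_pos, minus_pos)``.

    CCWGG is its own reverse-complement family (revcomp(CCAGG) = CCTGG), so a
    single overlapping scan of the plus strand finds every dyad: a motif at
    0-based ``i`` methylates the internal C at ``i+1`` (+) and ``i+3`` (-).
    """
    out = []
    for contig, seq in genome.items():
        for m in _DCM_RE.finditer(seq):
            i = m.start()
            out.append((contig, i + 1, i + 3))
    out.sort()
    return out


def scan_dcm_sites(genome: ReferenceGenome) -> list[tuple[str, int, str]]:
    """All Dcm internal-C site keys, sorted by (contig, pos)."""
    sites = []
    for contig, p, q in scan_dcm_dyads(genome):
        sites.append((contig, p, "+"))
        sites.append((contig, q, "-"))
    sites.sort(key=lambda k: (k[0], k[1], k[2]))
    return sites


def scan_cpg_dyads(genome: ReferenceGenome) -> list[tuple[str, int, int]]:
    """All CpG dyads as ``(contig, plus_pos, minus_pos=plus_pos+1)``."""
    out = []
    for contig, seq in genome.items():
        start = 0
        while True:
            i = seq.find("CG", start)
            if i < 0:
                break
            out.append((contig, i, i + 1))
            start = i + 1
    out.sort()
    return out


def resolve_regions(genome: ReferenceGenome, anchors: RegionSet, mode: str,
                    flank: int) -> RegionSet:
    """Derive analysis windows from gene anchors.

    ``tss_upstream`` gives the promoter-proximal window ``[TSS-flank, TSS)``
    for plus-strand genes and the strand-mirrored ``[TSS, TSS+flank)`` for
    minus-strand genes; ``tss_flank`` / ``tes_flank`` give symmetric windows
    around the TSS / TES.  Windows are clipped to contig bounds; anchors on
    missing contigs or with an off-contig anchor point are skipped with a
    logged warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if mode not in ("tss_upstream", "tss_flank", "tes_flank"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for contig, start, end, name, strand in anchors:
        if contig not in genome:
            log.warning("anchor %s: contig %s not in genome, skipped", name, contig)
            continue
        clen = genome.length(contig)
        if strand == "-":
            tss, tes = end - 1, start
        else:
            tss, tes = start, end - 1
        if not 0 <= tss < clen:
            log.warning("anchor %s: off-contig, skipped", name)
            continue
        if mode == "tss_upstream":
            lo, hi = (tss - flank, tss) if strand != "-" else (tss, tss + flank)
        elif mode == "tss_flank":
            lo, hi = tss - flank, tss + flank
        else:
            if not 0 <= tes < clen:
                log.warning("anchor %s: TES off-contig, skipped", name)
                continue
            lo, hi = tes - flank, tes + flank
        lo, hi = max(0, lo), min(clen, hi)
        if lo < hi:
            out.append((contig, lo, hi, name, strand))
    return RegionSet(out)
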