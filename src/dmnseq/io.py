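"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through pandas.
All user-facing tables use 1-based inclusive coordinates; BED keeps its native
0-based half-open convention.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Methylome, MethylSite, ReferenceGenome, RegionSet


class FormatError(ValueError):
    """Malformed input file (carries a line/record hint where available)."""


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> ReferenceGenome:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")  # wraps at 60 columns


def read_fastq(path):
    """Yield (name, sequence, quality); raises on truncated records."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


# ----------------------------------------------------------------------- BED

def read_bed(path) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED record needs >= 3 fields")
            contig = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from e
            if start >= end:
                raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else f"region_{ln}"
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append((contig, start, end, name, strand))
    return RegionSet(intervals)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name, strand in regions:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ----------------------------------------------------------------- methylome

def write_methylome_tsv(methylome: Methylome, path) -> None:
    """TSV with 1-based positions; dyad members share a dyad_id."""
    dyad_of = {}
    for i, (a, b) in enumerate(methylome.dyads):
        dyad_of[a] = i
        dyad_of[b] = i
    rows = []
    for key in sorted(methylome.sites):
        s = methylome.sites[key]
        rows.append((s.contig, s.pos + 1, s.strand, s.base_mod, s.beta,
                     dyad_of.get(key, -1)))
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "mod", "beta", "dyad_id"])
    df.to_csv(path, sep="\t", index=False)


def read_methylome_tsv(path) -> Methylome:
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "pos", "strand", "mod", "beta"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: methylome TSV needs columns {sorted(required)}")
    me = Methylome()
    if "dyad_id" in df.columns:
        paired = df[df["dyad_id"] >= 0]
        for _, grp in paired.groupby("dyad_id"):
            if len(grp) != 2:
                raise FormatError(f"{path}: dyad_id {grp['dyad_id'].iloc[0]} has {len(grp)} members")
            g = grp.sort_values("pos")
            me.add_dyad(str(g["contig"].iloc[0]), int(g["pos"].iloc[0]) - 1,
                        int(g["pos"].iloc[1]) - 1, float(g["beta"].iloc[0]),
                        str(g["mod"].iloc[0]))
        rest = df[df["dyad_id"] < 0]
    else:
        rest = df
    for _, row in rest.iterrows():
        me.add_site(MethylSite(str(row["contig"]), int(row["pos"]) - 1,
                               str(row["strand"]), float(row["beta"]), str(row["mod"])))
    return me


# ----------------------------------------------------------------------- SAM

def write_sam(truth: pd.DataFrame, genome: ReferenceGenome, path) -> None:
    """Write placed reads as a minimal single-end SAM (MAPQ fixed at 60)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": genome.length(name)} for name in genome.names],
    }
    tid = {name: i for i, name in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in truth.itertuples(index=False):
            a = pysam.AlignedSegment()
            a.query_name = row.read_id
            start, end = int(row.r1_start), int(row.r1_end)
            seq = genome.sequence(row.contig)[start:end]
            if row.strand == "-":
                from .genome import revcomp

                seq = revcomp(seq)
            a.query_sequence = seq
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.contig]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{end - start}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * (end - start))
            out.write(a)


def read_sam_starts(path) -> pd.DataFrame:
    """Alignment spans from a SAM/BAM: contig, r1_start, r1_end, strand."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.is_paired and not a.is_read1:
                continue
            rows.append((a.reference_name, a.reference_start, a.reference_end,
                         "-" if a.is_reverse else "+"))
    return pd.DataFrame(rows, columns=["contig", "r1_start", "r1_end", "strand"])


# --------------------------------------------------------------------- misc

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
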