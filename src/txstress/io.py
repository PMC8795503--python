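"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic files use the UCSC conventions: BED and bedGraph are 0-based
half-open; chrom.sizes is a two-column name/length TSV. CNC BED files
carry the gain/loss class in the BED name field. FASTA goes through
Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeLayout, GenomicInterval, RegionSet
from .pausing import CoverageTrack, GeneModel

__all__ = [
    "read_chrom_sizes", "write_chrom_sizes",
    "read_bed", "write_bed",
    "read_bedgraph", "write_bedgraph",
    "read_fasta", "write_fasta",
    "read_gene_table", "write_gene_table",
    "read_probe_table", "write_probe_table",
    "read_ct_table", "write_ct_table",
]


def read_chrom_sizes(path: str | Path, mask: RegionSet | None = None) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout(dict(zip(df["chrom"], df["length"].astype(int))), mask=mask)


def write_chrom_sizes(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path, genome: GenomeLayout | None = None, name: str = "") -> RegionSet:
    """BED3/BED6 reader; a name field of 'gain'/'loss' becomes the cnc_class."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            cls = fields[3] if len(fields) >= 4 and fields[3] in ("gain", "loss") else None
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), cnc_class=cls))
    return RegionSet(intervals, genome=genome, name=name or Path(path).stem)


def write_bed(regions: RegionSet, path: str | Path, scores: Iterable[float] | None = None) -> None:
    """BED writer; emits BED6 when intervals carry a class (name=class, score column)."""
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for k, iv in enumerate(regions):
            if iv.cnc_class is not None or scores is not None:
                score = scores[k] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.cnc_class or '.'}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: str | Path, genome: GenomeLayout, bin_width: int) -> CoverageTrack:
    """Fixed-bin bedGraph reader; intervals must align to the bin grid."""
    values = {c: np.zeros(int(np.ceil(l / bin_width)), dtype=float) for c, l in genome.chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     comment="#", dtype={"chrom": str})
    for chrom, s, e, v in df.itertuples(index=False):
        if chrom not in values:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        if s % bin_width or (e % bin_width and e != genome.chrom_sizes[chrom]):
            raise ValueError(f"bedGraph interval {chrom}:{s}-{e} not aligned to {bin_width}-bp bins")
        values[chrom][s // bin_width: int(np.ceil(e / bin_width))] = v
    return CoverageTrack(values, bin_width=bin_width)


def write_bedgraph(track: CoverageTrack, path: str | Path, genome: GenomeLayout | None = None) -> None:
    """Writes one line per run of equal-valued bins; zero runs are kept explicit."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            limit = genome.chrom_sizes[chrom] if genome is not None else len(v) * bw
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bw}\t{min(e * bw, limit)}\t{v[s]:g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Gene models from a TSV with explicit tss/tes/strand columns, or BED6.

    BED6 input is converted with the package convention: '+' genes have
    TSS = start, TES = end; '-' genes have TSS = end, TES = start.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return [
            GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tes))
            for r in df.itertuples(index=False)
        ]
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            start, end = int(start), int(end)
            if strand == "+":
                genes.append(GeneModel(name, chrom, "+", start, end))
            else:
                genes.append(GeneModel(name, chrom, "-", end, start))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path):
    from .cnc import ProbeTable

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return ProbeTable(df)


def write_probe_table(probe_table, path: str | Path) -> None:
    probe_table.df.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "region", "antibody", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
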