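"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA and FASTQ go through Biopython; the FASTA index (.fai) is produced with
pyfaidx.  BED flavors are tab-separated text: BED6 for genes and fragments,
BED4 (label in column 4) for chromatin-state segmentations, BED4 with a
summit offset for DNase peaks.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignedFragment,
    ChromatinSegmentation,
    DNasePeak,
    DNasePeakSet,
    ExcisionTruthRecord,
    GeneModel,
    RawRead,
    SyntheticGenome,
)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> SyntheticGenome:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chroms[rec.id] = str(rec.seq).upper()
    return SyntheticGenome(chroms)


def write_fasta(genome: SyntheticGenome, path: str | Path, line_width: int = 70,
                index: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    if index:
        import pyfaidx

        pyfaidx.Faidx(str(path))  # writes <path>.fai
    return path


def read_fastq(path: str | Path) -> list[RawRead]:
    with _open_text(path) as fh:
        return [
            RawRead(
                rec.id,
                str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")
    return path


# ---------------------------------------------------------------------------
# BED flavors


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            score = 1 if g.expressed else 0
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t{score}\t{g.strand}\n")
    return path


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            genes.append(
                GeneModel(
                    id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    expressed=bool(int(score)),
                )
            )
    return genes


def write_states_bed(segmentation: ChromatinSegmentation, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, label in segmentation.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
    return path


def read_states_bed(path: str | Path, states: Sequence[str] | None = None) -> ChromatinSegmentation:
    intervals = []
    seen: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, label = line.rstrip("\n").split("\t")[:4]
            intervals.append((chrom, int(start), int(end), label))
            if label not in seen:
                seen.append(label)
    vocab = tuple(states) if states is not None else tuple(seen)
    return ChromatinSegmentation(intervals=intervals, states=vocab)


def write_peaks_bed(peaks: DNasePeakSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.summit_offset}\n")
    return path


def read_peaks_bed(path: str | Path) -> DNasePeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if len(fields) > 3 and fields[3].strip():
                offset = int(fields[3])
            else:
                offset = (end - start) // 2
            peaks.append(DNasePeak(chrom, start, end, offset))
    return DNasePeakSet(peaks)


def write_fragments_bed(fragments: Sequence[AlignedFragment], path: str | Path) -> Path:
    from .preprocess import fragments_to_bed

    path = Path(path)
    with open(path, "w") as fh:
        for line in fragments_to_bed(fragments):
            fh.write(line + "\n")
    return path


def read_fragments_bed(path: str | Path) -> list[AlignedFragment]:
    fragments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            fragments.append(AlignedFragment(chrom, int(start), int(end), strand, name))
    return fragments


# ---------------------------------------------------------------------------
# Truth table


TRUTH_COLUMNS = ["read_id", "chrom", "strand", "start", "end", "lesion_pos", "offset"]


def write_truth_tsv(truth: Sequence[ExcisionTruthRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(t) for t in truth], columns=TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_truth_tsv(path: str | Path) -> list[ExcisionTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExcisionTruthRecord(
            read_id=str(r.read_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            start=int(r.start),
            end=int(r.end),
            lesion_pos=int(r.lesion_pos),
            offset=int(r.offset),
        )
        for r in df.itertuples(index=False)
    ]
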