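"""Reading and writing the pipeline's file formats.

FASTA/FASTQ go through Biopython; loci tables are GFF3-like text; tag
tables, truth tables and reports are TSV/JSON.  FASTQ is Sanger
Phred+33 throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cleaning import CleanTag, CleaningReport, FastqRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_gff3",
    "write_tags_tsv",
    "read_tags_tsv",
    "write_report_json",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse a Sanger FASTQ file; malformed records raise with the file named."""
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def write_gff3(
    path: str | Path,
    features: Iterable[tuple[str, str, int, int, str, str]],
    source: str = "mirseed",
) -> None:
    """Write (chrom, feature type, start0, end, strand, id) rows as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ftype, start, end, strand, fid in features:
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid}\n"
            )


def write_tags_tsv(path: str | Path, tags: Sequence[CleanTag]) -> None:
    pd.DataFrame(
        [(t.sequence, t.count_control, t.count_treatment) for t in tags],
        columns=["sequence", "count_control", "count_treatment"],
    ).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path: str | Path) -> list[CleanTag]:
    df = pd.read_csv(path, sep="\t")
    return [
        CleanTag(r.sequence, int(r.count_control), int(r.count_treatment))
        for r in df.itertuples()
    ]


def write_report_json(path: str | Path, report: CleaningReport) -> None:
    payload = {
        "raw_total": report.raw_total,
        "removed": report.removed,
        "clean_total": report.clean_total,
        "length_histogram": {str(k): v for k, v in report.length_histogram.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
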