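"""FASTA/GFF3/TSV I/O helpers (Biopython-backed FASTA, 60-column wrap)."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Dict[str, str], path, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


GffRow = Tuple[str, str, str, int, int, str, str, str]


def write_gff3(rows: Iterable[GffRow], path) -> None:
    """Write (seqid, source, type, start, end, score, strand, attributes) rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n"
            )
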