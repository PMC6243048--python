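"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ (plain or gzipped) go through Biopython; SAM ingestion goes
through pysam and extracts only what the similarity and CCS rules need
(CIGAR, NM, target, role).  Qualities are preserved on round trip but unused
by the graph.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)``; qualities are parsed but not returned."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> list[tuple[str, str]]:
    """Mate-synchronised read pairs from two FASTQ files."""
    pairs = []
    for (id1, s1), (id2, s2) in zip(read_fastq(r1), read_fastq(r2), strict=True):
        pairs.append((s1, s2))
    return pairs


def write_fastq_pairs(
    r1: str | Path, r2: str | Path, pairs: Iterable[tuple[str, str]], prefix: str = "read"
) -> None:
    with open(r1, "w") as f1, open(r2, "w") as f2:
        for i, (m1, m2) in enumerate(pairs):
            f1.write(f"@{prefix}_{i}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{prefix}_{i}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def read_sam_alignments(path: str | Path):
    """CCS alignment records from a SAM file (CIGAR + NM only).

    Returns :class:`isocore.longread.CcsAlignment` objects; unmapped records
    are skipped.
    """
    import pysam

    from .longread import CcsAlignment

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            if rec.is_supplementary:
                role = "supplementary"
            elif rec.is_secondary:
                role = "secondary"
            else:
                role = "primary"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                CcsAlignment(
                    read_id=rec.query_name,
                    target_id=rec.reference_name,
                    role=role,
                    edit_distance=int(nm),
                    cigar=rec.cigarstring,
                )
            )
    return out


def read_locus_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: transcript_id <tab> locus."""
    out = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed locus map line {lineno}: {line!r}")
            out[fields[0]] = fields[1]
    return out


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
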