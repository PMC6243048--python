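"""Access to the packaged DAL19 assembly benchmark records.

These are the published best-match alignments of three assembly strategies
(Oases, Trinity, and the colored-graph/bootstrap method on one and on nine bud
samples) against the cloned DAL19 isoform references.  Each record carries the
reference length, the alignment CIGAR, and the published similarity score.
Records marked evaluable can be recomputed exactly from the CIGAR alone (they
contain only M/clip operations, or indels with zero substitutions); the rest
would require unpublished per-alignment substitution counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .evaluation import SimilarityResult, score_alignment


@dataclass(frozen=True)
class BenchmarkRecord:
    reference: str
    reference_length: int
    assembly: str
    similarity: float
    cigar: str
    evaluable: bool


def load_benchmarks() -> list[BenchmarkRecord]:
    text = (
        resources.files("isocore.data")
        .joinpath("dal19_benchmarks.tsv")
        .read_text(encoding="utf-8")
    )
    records = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        records.append(
            BenchmarkRecord(
                reference=row["reference"],
                reference_length=int(row["reference_length"]),
                assembly=row["assembly"],
                similarity=float(row["similarity"]),
                cigar=row["cigar"],
                evaluable=row["evaluable"] == "1",
            )
        )
    return records


def recompute_similarity(record: BenchmarkRecord) -> SimilarityResult:
    """Similarity recomputed from the record's CIGAR under zero substitutions."""
    return score_alignment(
        record.cigar,
        record.reference,
        record.reference_length,
        substitution_mismatches=0,
        assembled_id=record.assembly,
    )
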