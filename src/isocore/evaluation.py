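"""CIGAR-based match-length similarity between assembled and reference transcripts.

The score for an assembled transcript against a reference is

    similarity = match_length / reference_length,

where ``match_length`` is the number of aligned bases counted from the CIGAR
string (sum of M and = operation lengths) minus the number of substitution
mismatches.  Soft/hard clips, insertions, deletions and skips contribute
nothing.  Note the direction of the ratio: the denominator is the reference
length, which is what reproduces the published DAL19 per-isoform scores; a
perfect full-length reconstruction scores 1.00 and a truncated one scores the
covered fraction.

When ingesting SAM records, the NM tag counts substitutions *and* indel bases
(SAMv1), so the substitution count is recovered as
``max(0, NM - inserted - deleted bases)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

from .dna import revcomp

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops whose lengths count as aligned matches before mismatch subtraction
_MATCH_OPS = frozenset("M=")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Tokenize a SAMv1 CIGAR string into (length, op) pairs.

    Raises ``ValueError`` on malformed input (including trailing garbage).
    """
    if not cigar or cigar == "*":
        raise ValueError(f"empty CIGAR {cigar!r}")
    pos = 0
    out = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
    return out


def cigar_match_length(cigar: str, substitution_mismatches: int = 0) -> int:
    """Aligned-base count: sum of M/= op lengths minus substitution mismatches.

    Never negative; I/D/N/S/H ops contribute nothing.
    """
    if substitution_mismatches < 0:
        raise ValueError("substitution_mismatches must be >= 0")
    total = sum(n for n, op in parse_cigar(cigar) if op in _MATCH_OPS)
    return max(0, total - substitution_mismatches)


def substitutions_from_nm(cigar: str, nm: int) -> int:
    """Substitution count from an NM tag: NM minus inserted and deleted bases."""
    indel = sum(n for n, op in parse_cigar(cigar) if op in "ID")
    return max(0, nm - indel)


@dataclass
class SimilarityResult:
    reference_id: str
    reference_length: int
    match_length: int
    similarity: float
    cigar: str = ""
    assembled_id: str = ""

    @property
    def rounded(self) -> float:
        """Similarity at presentation precision (two decimals)."""
        return round(self.similarity, 2)


def similarity_proportion(match_length: int, target_length: int) -> float:
    """``match_length / target_length``, capped at 1.0 (with a warning when an
    M-op-spanning-indel alignment pushes the raw ratio above 1)."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    ratio = match_length / target_length
    if ratio > 1.0:
        logger.warning(
            "match length %d exceeds target length %d; capping similarity at 1.0",
            match_length,
            target_length,
        )
        return 1.0
    return ratio


def score_alignment(
    cigar: str,
    reference_id: str,
    reference_length: int,
    substitution_mismatches: int = 0,
    assembled_id: str = "",
) -> SimilarityResult:
    ml = cigar_match_length(cigar, substitution_mismatches)
    return SimilarityResult(
        reference_id,
        reference_length,
        ml,
        similarity_proportion(ml, reference_length),
        cigar,
        assembled_id,
    )


def _align_match_length(query: str, target: str) -> tuple[int, str]:
    """Match length of the best semi-global alignment of ``query`` within
    ``target`` (edlib infix mode, extended CIGAR), as (match_length, cigar)."""
    import edlib

    res = edlib.align(query, target, mode="HW", task="path")
    cigar = res.get("cigar") or ""
    if not cigar:
        return 0, ""
    match = sum(n for n, op in parse_cigar(cigar) if op == "=")
    return match, cigar


def best_match_similarity(
    assembled: Mapping[str, str], references: Mapping[str, str]
) -> dict[str, SimilarityResult]:
    """For each reference, the maximal match length over all assembled
    transcripts (both strands, query-in-target and target-in-query infix
    alignments), expressed as a similarity proportion.

    A reference matched by nothing gets similarity 0 with an empty CIGAR.
    """
    if not assembled or not references:
        raise ValueError("both sequence sets must be non-empty")
    out: dict[str, SimilarityResult] = {}
    for ref_id in sorted(references):
        ref = references[ref_id]
        best = SimilarityResult(ref_id, len(ref), 0, 0.0)
        for asm_id in sorted(assembled):
            seq = assembled[asm_id]
            for oriented in (seq, revcomp(seq)):
                for q, t in ((oriented, ref), (ref, oriented)):
                    ml, cigar = _align_match_length(q, t)
                    if ml > best.match_length:
                        best = SimilarityResult(
                            ref_id,
                            len(ref),
                            ml,
                            similarity_proportion(ml, len(ref)),
                            cigar,
                            asm_id,
                        )
        out[ref_id] = best
    return out
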