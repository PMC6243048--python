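"""Long-read (CCS) threading, filtering, grouping, and unique-locus counting.

Circular consensus (CCS) reads serve as independent full-length transcript
evidence: they are threaded into the short-read graph as extra colors for
joint visualization, and counted per locus when all their alignments agree on
a single locus.  The alignment-record rules are the contribution here; records
may come from an external mapper (SAM) or from the internal semi-global
aligner.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dna import revcomp
from .graph import ColoredDBG, build_graph, flatten_colors, merge_graphs
from .unitigs import collapse_unitigs

logger = logging.getLogger(__name__)

ROLES = ("primary", "secondary", "supplementary")


@dataclass(frozen=True)
class CcsAlignment:
    """One alignment record of a CCS read against a transcript or region."""

    read_id: str
    target_id: str
    role: str  # primary | secondary | supplementary
    edit_distance: int
    cigar: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}")
        if self.edit_distance < 0:
            raise ValueError("edit distance must be >= 0")


def filter_ccs_alignments(
    alns: Iterable[CcsAlignment], max_nm_exclusive: int = 5
) -> list[CcsAlignment]:
    """Keep alignments with edit distance strictly below ``max_nm_exclusive``
    (default: keep NM <= 4, drop NM >= 5)."""
    return [a for a in alns if a.edit_distance < max_nm_exclusive]


def group_ccs_by_region(
    alns: Iterable[CcsAlignment],
    region_of_target: Mapping[str, str],
    regions: Sequence[str] = ("alpha", "beta"),
) -> dict[str, list[str]]:
    """Assign each read to one mutually exclusive 5' region group or "neither".

    A read belongs to a region group when any of its primary or supplementary
    alignments hits a target mapped to that region; reads hitting several of
    the named regions are contradictory — they are excluded and logged under
    the "excluded" key.  Reads aligning only elsewhere (e.g., only the shared
    core) fall in "neither".
    """
    hits: dict[str, set[str]] = defaultdict(set)
    reads: set[str] = set()
    for a in alns:
        reads.add(a.read_id)
        if a.role in ("primary", "supplementary"):
            region = region_of_target.get(a.target_id)
            if region in regions:
                hits[a.read_id].add(region)
    groups: dict[str, list[str]] = {r: [] for r in regions}
    groups["neither"] = []
    groups["excluded"] = []
    for read in sorted(reads):
        h = hits.get(read, set())
        if len(h) > 1:
            logger.warning("read %s matches several exclusive regions %s", read, sorted(h))
            groups["excluded"].append(read)
        elif h:
            groups[next(iter(h))].append(read)
        else:
            groups["neither"].append(read)
    return groups


def count_unique_locus_reads(
    alns: Iterable[CcsAlignment], locus_of_target: Mapping[str, str]
) -> dict[str, int]:
    """Per-locus counts of reads whose alignments all agree on one locus.

    A read contributes 1 to locus L iff every surviving primary or secondary
    alignment of that read targets a transcript assigned to L; reads spanning
    two or more loci, or with no surviving alignment, contribute nothing.
    Duplicated records and record order do not affect the counts.
    """
    loci_of_read: dict[str, set[str]] = defaultdict(set)
    for a in alns:
        if a.role in ("primary", "secondary"):
            loci_of_read[a.read_id].add(locus_of_target[a.target_id])
    counts: dict[str, int] = defaultdict(int)
    for read in loci_of_read:
        loci = loci_of_read[read]
        if len(loci) == 1:
            counts[next(iter(loci))] += 1
    return dict(counts)


def align_ccs_reads(
    reads: Mapping[str, str],
    references: Mapping[str, str],
    max_nm_exclusive: int | None = None,
    contained: str = "query",
) -> list[CcsAlignment]:
    """Semi-global (infix) alignments of reads against reference sequences.

    ``contained="query"`` aligns each read inside each reference (reads are
    near-full-length transcripts); ``contained="reference"`` aligns each
    reference region inside each read (for locating short exon regions in
    long reads).  Both strands are tried and the better one kept.  Per read,
    the lowest-edit-distance hit is the primary alignment and all other finite
    hits are secondary; ``max_nm_exclusive`` optionally applies the strict
    edit-distance filter up front.
    """
    import edlib

    out: list[CcsAlignment] = []
    for read_id in sorted(reads):
        seq = reads[read_id]
        hits: list[tuple[int, str, str]] = []
        for ref_id in sorted(references):
            ref = references[ref_id]
            best_d, best_c = None, ""
            for oriented in (seq, revcomp(seq)):
                q, t = (oriented, ref) if contained == "query" else (ref, oriented)
                res = edlib.align(q, t, mode="HW", task="path")
                d = res["editDistance"]
                if d >= 0 and (best_d is None or d < best_d):
                    best_d, best_c = d, res.get("cigar") or ""
            if best_d is not None:
                hits.append((best_d, ref_id, best_c))
        hits.sort()
        for rank, (d, ref_id, cigar) in enumerate(hits):
            if max_nm_exclusive is not None and d >= max_nm_exclusive:
                continue
            role = "primary" if rank == 0 else "secondary"
            out.append(CcsAlignment(read_id, ref_id, role, d, cigar))
    return out


def thread_ccs(
    graph: ColoredDBG,
    ccs_groups: Mapping[str, Sequence[str]],
    prune_coverage: float | None = None,
) -> ColoredDBG:
    """Join CCS reads into the graph, one color per group, then prune.

    Each group's reads are built as separate single-read colors and flattened
    into one group color (coverages add, edges union), mirroring how separate
    long-read graphs are merged.  After joining, unitigs of the combined graph
    whose mean coverage summed over all colors is strictly below
    ``prune_coverage`` (default ``params.ccs_prune_coverage``) are removed.
    Short-read-color coverages on surviving nodes are untouched.
    """
    params = graph.params
    if prune_coverage is None:
        prune_coverage = params.ccs_prune_coverage
    joined = graph
    for group in sorted(ccs_groups):
        reads = ccs_groups[group]
        if not reads:
            g = ColoredDBG(params, [group])
        else:
            per_read = [
                build_graph([r], params, f"{group}/{i}") for i, r in enumerate(reads)
            ]
            g = merge_graphs(per_read)
            g = flatten_colors(g, g.colors, group)
        joined = merge_graphs([joined, g])
    if prune_coverage <= 0:
        return joined
    ug = collapse_unitigs(joined)
    keep: set[str] = set()
    for u in ug.unitigs.values():
        total = sum(u.mean_coverage.get(c, 0.0) for c in joined.colors)
        if total >= prune_coverage:
            keep.update(u.kmers)
    return joined.subset(keep)
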