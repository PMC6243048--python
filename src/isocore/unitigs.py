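"""Unitig collapsing and coverage filtering.

A unitig is a maximal run of adjacent k-mers in which every internal node has
exactly one incoming and one outgoing neighbor (with respect to a designated
set of *collapse colors* — by default the short-read sample color only, so
that seed or long-read colors cannot introduce phantom junctions).  Unitig
sequences are reported in canonical orientation (the lexicographically smaller
of sequence and reverse complement), which makes output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dna import revcomp
from .graph import ColoredDBG, GraphParams

Orient = str  # "+" or "-"


def _flip(o: Orient) -> Orient:
    return "-" if o == "+" else "+"


@dataclass
class Unitig:
    """A collapsed non-branching path.

    ``kmers`` lists the constituent canonical k-mers in path order of the
    reported (canonical) sequence orientation.
    """

    uid: int
    sequence: str
    kmers: list[str]
    mean_coverage: dict[str, float]

    @property
    def kmer_count(self) -> int:
        return len(self.kmers)

    def end_kmer(self, orient: Orient, k: int) -> str:
        """Oriented last k-mer when the unitig is read in ``orient``."""
        if orient == "+":
            return self.sequence[-k:]
        return revcomp(self.sequence[:k])


class UnitigGraph:
    """Unitigs plus per-color directed links between unitig ends.

    A link ``(u, uo) -> (v, vo)`` means: reading unitig ``u`` in orientation
    ``uo``, its last k-mer is followed (k-1 overlap) by the first k-mer of
    ``v`` read in orientation ``vo``.
    """

    def __init__(self, dbg: ColoredDBG) -> None:
        self.dbg = dbg
        self.params: GraphParams = dbg.params
        self.unitigs: dict[int, Unitig] = {}
        self.kmer_to_unitig: dict[str, int] = {}
        self.collapse_colors: list[str] = list(dbg.colors)
        # color -> {(uid, orient): set[(vid, orient)]}
        self.links: dict[str, dict[tuple[int, Orient], set[tuple[int, Orient]]]] = {}

    @property
    def colors(self) -> list[str]:
        return self.dbg.colors

    def _add_link(self, color: str, u: tuple[int, Orient], v: tuple[int, Orient]) -> None:
        adj = self.links.setdefault(color, {})
        adj.setdefault(u, set()).add(v)
        adj.setdefault((v[0], _flip(v[1])), set()).add((u[0], _flip(u[1])))

    def successors(
        self, uid: int, orient: Orient, colors: Sequence[str] | None = None
    ) -> set[tuple[int, Orient]]:
        use = self.colors if colors is None else colors
        out: set[tuple[int, Orient]] = set()
        for c in use:
            out |= self.links.get(c, {}).get((uid, orient), set())
        return out

    def predecessors(
        self, uid: int, orient: Orient, colors: Sequence[str] | None = None
    ) -> set[tuple[int, Orient]]:
        return {
            (v, _flip(vo)) for v, vo in self.successors(uid, _flip(orient), colors)
        }


def _orient_of_entry(
    ug: UnitigGraph, canon: str, oriented: str
) -> tuple[int, Orient] | None:
    """Which unitig, in which orientation, *starts* with this oriented k-mer.

    Returns None when the k-mer sits mid-unitig (possible when a link color was
    not among the collapse colors); such attachments are not end links.
    """
    k = ug.params.k
    uid = ug.kmer_to_unitig[canon]
    unitig = ug.unitigs[uid]
    if unitig.kmers[0] == canon and unitig.sequence[:k] == oriented:
        return uid, "+"
    if unitig.kmers[-1] == canon and revcomp(unitig.sequence[-k:]) == oriented:
        return uid, "-"
    return None


def collapse_unitigs(
    graph: ColoredDBG,
    collapse_colors: Sequence[str] | None = None,
    allowed: set[str] | None = None,
) -> UnitigGraph:
    """Collapse maximal non-branching runs into unitigs.

    ``collapse_colors`` designates the edge colors that define adjacency
    (default: all colors).  ``allowed`` optionally restricts the node set; the
    decomposition then acts on the induced subgraph.  Every (allowed) k-mer
    lands in exactly one unitig; isolated k-mers become single-k-mer unitigs.
    """
    if collapse_colors is None:
        collapse_colors = list(graph.colors)
    nodes = set(graph.nodes) if allowed is None else set(allowed)

    def succs(canon: str, forward: bool) -> list[tuple[str, bool]]:
        return [
            (c, f)
            for c, f in graph.successors(canon, forward, collapse_colors)
            if c in nodes
        ]

    ug = UnitigGraph(graph)
    visited: set[str] = set()
    uid = 0
    for start in sorted(nodes):
        if start in visited:
            continue
        path: list[tuple[str, bool]] = [(start, True)]
        in_path = {start}
        # extend forward, then backward, stopping at any junction
        for direction in (1, 0):
            while True:
                canon, fwd = path[-1] if direction else path[0]
                nxt = succs(canon, fwd) if direction else [
                    (c, not f) for c, f in succs(canon, not fwd)
                ]
                if len(nxt) != 1:
                    break
                ncanon, nfwd = nxt[0]
                if ncanon in in_path or ncanon in visited:
                    break
                back = succs(ncanon, not nfwd) if direction else succs(ncanon, nfwd)
                if len(back) != 1:
                    break
                if direction:
                    path.append((ncanon, nfwd))
                else:
                    path.insert(0, (ncanon, nfwd))
                in_path.add(ncanon)
        k = graph.params.k
        seq_parts = [path[0][0] if path[0][1] else revcomp(path[0][0])]
        for canon, fwd in path[1:]:
            oriented = canon if fwd else revcomp(canon)
            seq_parts.append(oriented[-1])
        seq = "".join(seq_parts)
        kmers = [c for c, _ in path]
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            kmers = kmers[::-1]
        mean_cov = {
            color: sum(graph.nodes[c].coverage.get(color, 0) for c in kmers)
            / len(kmers)
            for color in graph.colors
        }
        ug.unitigs[uid] = Unitig(uid, seq, kmers, mean_cov)
        for c in kmers:
            ug.kmer_to_unitig[c] = uid
            visited.add(c)
        uid += 1

    # links: for each unitig end, follow graph edges per color
    k = graph.params.k
    for u in ug.unitigs.values():
        for orient in ("+", "-"):
            end_canon = u.kmers[-1] if orient == "+" else u.kmers[0]
            end_oriented = u.end_kmer(orient, k)
            end_fwd = end_oriented == end_canon
            for color in graph.colors:
                for ncanon, nfwd in graph.successors(end_canon, end_fwd, [color]):
                    if ncanon not in nodes:
                        continue
                    noriented = ncanon if nfwd else revcomp(ncanon)
                    v = _orient_of_entry(ug, ncanon, noriented)
                    if v is None:
                        continue  # mid-unitig attachment from a non-collapse color
                    ug._add_link(color, (u.uid, orient), v)
    ug.collapse_colors = list(collapse_colors)
    return ug


def filter_unitigs_by_mean_coverage(
    ug: UnitigGraph,
    threshold: float,
    color: str,
    recollapse: bool = True,
) -> UnitigGraph:
    """Remove unitigs whose mean coverage in ``color`` is strictly below
    ``threshold`` (a mean of exactly ``threshold`` survives).

    By default the survivors are re-collapsed, since removing a branch can
    merge formerly distinct runs; the filter is idempotent either way because
    a merged unitig's mean is a weighted average of means already at or above
    the threshold.
    """
    if color not in ug.colors:
        raise ValueError(f"unknown color {color!r}")
    survivors = [
        u for u in ug.unitigs.values() if u.mean_coverage.get(color, 0.0) >= threshold
    ]
    keep_kmers = {c for u in survivors for c in u.kmers}
    if recollapse:
        return collapse_unitigs(ug.dbg, ug.collapse_colors, allowed=keep_kmers)
    out = UnitigGraph(ug.dbg)
    keep_ids = {u.uid for u in survivors}
    out.unitigs = {u.uid: u for u in survivors}
    out.kmer_to_unitig = {c: u.uid for u in survivors for c in u.kmers}
    for colorlabel, adj in ug.links.items():
        for (uid, uo), targets in adj.items():
            if uid not in keep_ids:
                continue
            kept = {(v, vo) for v, vo in targets if v in keep_ids}
            if kept:
                out.links.setdefault(colorlabel, {})[(uid, uo)] = kept
    return out
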