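"""Colored De Bruijn graph over canonical k-mers.

Each data source (a short-read sample, a seed/core-region sequence, a group of
long CCS reads) is a *color* that carries its own k-mer coverage counts and its
own directed base edges on a shared node set.  Nodes are canonical k-mers;
edges are stored relative to the canonical orientation as incoming/outgoing
base sets, Cortex style, so each node has at most four in- and four out-edges
per color.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dna import COMP, canonicalize, iter_valid_kmers, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphParams:
    """Graph-construction and cleaning parameters.

    k
        odd k-mer length in bases (default 47, matching 2x125 bp short reads).
    min_unitig_mean_coverage
        unitigs with mean coverage strictly below this are removed (default 4).
    ccs_prune_coverage
        after joining CCS-read colors, unitigs with total mean coverage
        strictly below this are pruned (default 2).
    """

    k: int = 47
    min_unitig_mean_coverage: float = 4.0
    ccs_prune_coverage: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.min_unitig_mean_coverage < 0 or self.ccs_prune_coverage < 0:
            raise ValueError("coverage thresholds must be >= 0")


@dataclass
class KmerNode:
    """One canonical k-mer with per-color coverage and per-color base edges.

    ``in_bases[color]`` / ``out_bases[color]`` hold the neighbor bases in the
    node's canonical orientation: an out-edge with base ``b`` points to the
    k-mer ``canonical[1:] + b``; an in-edge with base ``b`` comes from
    ``b + canonical[:-1]``.
    """

    coverage: dict[str, int] = field(default_factory=dict)
    in_bases: dict[str, set[str]] = field(default_factory=dict)
    out_bases: dict[str, set[str]] = field(default_factory=dict)

    def coverage_of(self, color: str) -> int:
        return self.coverage.get(color, 0)


class ColoredDBG:
    """Colored De Bruijn graph of canonical k-mers."""

    def __init__(self, params: GraphParams, colors: Iterable[str] = ()) -> None:
        self.params = params
        self.colors: list[str] = []
        self.nodes: dict[str, KmerNode] = {}
        for c in colors:
            self.add_color(c)

    # -- construction -----------------------------------------------------

    def add_color(self, color: str) -> None:
        if color in self.colors:
            raise ValueError(f"duplicate color label {color!r}")
        self.colors.append(color)

    def _node(self, canon: str) -> KmerNode:
        node = self.nodes.get(canon)
        if node is None:
            node = self.nodes[canon] = KmerNode()
        return node

    def add_sequence(self, seq: str, color: str) -> int:
        """Count every valid k-mer of ``seq`` (either orientation) into ``color``
        and record the (k+1)-mer edges.  Returns the number of k-mers added."""
        if color not in self.colors:
            raise ValueError(f"unknown color {color!r}")
        k = self.params.k
        prev: tuple[str, str] | None = None  # (canonical, oriented kmer)
        prev_pos = -2
        n_added = 0
        for pos, kmer in iter_valid_kmers(seq, k):
            canon, flipped = canonicalize(kmer)
            node = self._node(canon)
            node.coverage[color] = node.coverage.get(color, 0) + 1
            n_added += 1
            if prev is not None and pos == prev_pos + 1:
                pcanon, pkmer = prev
                # edge pkmer -> kmer in read orientation
                pnode = self.nodes[pcanon]
                if pkmer == pcanon:
                    pnode.out_bases.setdefault(color, set()).add(kmer[-1])
                else:
                    pnode.in_bases.setdefault(color, set()).add(COMP[kmer[-1]])
                if not flipped:
                    node.in_bases.setdefault(color, set()).add(pkmer[0])
                else:
                    node.out_bases.setdefault(color, set()).add(COMP[pkmer[0]])
            prev = (canon, kmer)
            prev_pos = pos
        return n_added

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def successors(
        self, canon: str, forward: bool, colors: Sequence[str] | None = None
    ) -> list[tuple[str, bool]]:
        """Oriented successors of a node.

        ``forward`` selects the canonical (+) or reverse-complement (-)
        orientation.  Returns ``(canonical_neighbor, neighbor_forward)`` pairs,
        sorted by extension base for determinism, restricted to ``colors``
        (default: all colors).
        """
        node = self.nodes[canon]
        use = self.colors if colors is None else colors
        bases: set[str] = set()
        for c in use:
            if forward:
                bases |= node.out_bases.get(c, set())
            else:
                bases |= {COMP[b] for b in node.in_bases.get(c, set())}
        oriented = canon if forward else revcomp(canon)
        out = []
        for b in sorted(bases):
            nxt = oriented[1:] + b
            ncanon, nflip = canonicalize(nxt)
            if ncanon in self.nodes:
                out.append((ncanon, not nflip))
        return out

    def subset(self, keep: set[str]) -> "ColoredDBG":
        """Graph restricted to the canonical k-mers in ``keep``.

        Edges whose implied neighbor falls outside ``keep`` are dropped so the
        neighbor-presence invariant still holds.
        """
        sub = ColoredDBG(self.params, self.colors)
        for canon in keep:
            node = self.nodes[canon]
            new = KmerNode(coverage=dict(node.coverage))
            for color in self.colors:
                for b in node.out_bases.get(color, set()):
                    if canonicalize(canon[1:] + b)[0] in keep:
                        new.out_bases.setdefault(color, set()).add(b)
                for b in node.in_bases.get(color, set()):
                    if canonicalize(b + canon[:-1])[0] in keep:
                        new.in_bases.setdefault(color, set()).add(b)
            sub.nodes[canon] = new
        return sub


def build_graph(
    reads: Iterable[str], params: GraphParams, color: str
) -> ColoredDBG:
    """Build a single-color graph from a read collection.

    Coverage of each canonical k-mer equals the number of its occurrences, in
    either orientation, across the reads; an edge exists iff some read
    contains the corresponding (k+1)-mer.  Reads shorter than k (and non-ACGT
    windows) contribute nothing; a fully empty result is logged as a warning.
    """
    g = ColoredDBG(params, [color])
    n_reads = 0
    n_short = 0
    for read in reads:
        n_reads += 1
        if len(read) < params.k:
            n_short += 1
            continue
        g.add_sequence(read, color)
    if n_short:
        logger.info("skipped %d/%d reads shorter than k=%d", n_short, n_reads, params.k)
    if n_reads and not g.nodes:
        logger.warning("all %d reads yielded no k-mers at k=%d", n_reads, params.k)
    return g


def merge_graphs(graphs: Sequence[ColoredDBG]) -> ColoredDBG:
    """Union of node sets; each color's coverages and edges pass through unchanged.

    Requires identical k and pairwise-disjoint color labels.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    k = graphs[0].params.k
    for g in graphs[1:]:
        if g.params.k != k:
            raise ValueError(f"k mismatch: {g.params.k} != {k}")
    merged = ColoredDBG(graphs[0].params)
    for g in graphs:
        for color in g.colors:
            merged.add_color(color)  # raises on duplicates
        for canon, node in g.nodes.items():
            dst = merged._node(canon)
            for color in g.colors:
                if color in node.coverage:
                    dst.coverage[color] = node.coverage[color]
                if color in node.in_bases:
                    dst.in_bases[color] = set(node.in_bases[color])
                if color in node.out_bases:
                    dst.out_bases[color] = set(node.out_bases[color])
    return merged


def flatten_colors(
    graph: ColoredDBG, colors: Sequence[str], new_color: str
) -> ColoredDBG:
    """Merge a color subset into one color: coverages add, edges union.

    The merged colors are removed; other colors are untouched.
    """
    if not colors:
        raise ValueError("empty color subset")
    missing = [c for c in colors if c not in graph.colors]
    if missing:
        raise ValueError(f"colors not in graph: {missing}")
    keep = [c for c in graph.colors if c not in colors]
    if new_color in keep:
        raise ValueError(f"new color {new_color!r} collides with a kept color")
    out = ColoredDBG(graph.params, keep + [new_color])
    for canon, node in graph.nodes.items():
        new = KmerNode()
        for c in keep:
            if c in node.coverage:
                new.coverage[c] = node.coverage[c]
            if c in node.in_bases:
                new.in_bases[c] = set(node.in_bases[c])
            if c in node.out_bases:
                new.out_bases[c] = set(node.out_bases[c])
        cov = sum(node.coverage.get(c, 0) for c in colors)
        if cov:
            new.coverage[new_color] = cov
        inb: set[str] = set()
        outb: set[str] = set()
        for c in colors:
            inb |= node.in_bases.get(c, set())
            outb |= node.out_bases.get(c, set())
        if inb:
            new.in_bases[new_color] = inb
        if outb:
            new.out_bases[new_color] = outb
        out.nodes[canon] = new
    return out
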