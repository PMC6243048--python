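"""Seed-guided subgraph extraction and candidate-transcript enumeration.

The method anchors assembly at conserved *core regions* (for the focal MADS-box
gene DAL19 this is the four-exon region ψ shared by all isoforms): the
coverage-filtered unitig graph is traversed from every k-mer of each seed,
short tips are pruned, and every simple path from every incoming tip to every
outgoing tip becomes one candidate transcript.  Because simple paths cannot
repeat a unitig, candidates never contain cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dna import canonicalize, iter_valid_kmers, revcomp
from .unitigs import Orient, UnitigGraph, _flip

logger = logging.getLogger(__name__)


class PathExplosionError(RuntimeError):
    """Raised when tip-to-tip path enumeration exceeds the configured cap.

    Simple-path counts scale exponentially with the number of bubbles, so the
    enumerator fails loudly instead of silently truncating.
    """


@dataclass(frozen=True)
class SeedRegion:
    """A named anchor sequence (a core region or an exon region)."""

    name: str
    sequence: str

    def kmers(self, k: int) -> set[str]:
        """Canonical k-mer set of the seed."""
        return {canonicalize(km)[0] for _, km in iter_valid_kmers(self.sequence, k)}


@dataclass
class SeedSubgraph:
    """A connected component of the unitig graph containing seed k-mers."""

    ug: UnitigGraph
    unitig_ids: set[int]
    seed_names: list[str]
    seed_kmers: set[str]

    def successors(self, uid: int, orient: Orient) -> set[tuple[int, Orient]]:
        return {
            (v, vo)
            for v, vo in self.ug.successors(uid, orient)
            if v in self.unitig_ids
        }

    def predecessors(self, uid: int, orient: Orient) -> set[tuple[int, Orient]]:
        return {(v, _flip(vo)) for v, vo in self.successors(uid, _flip(orient))}

    def oriented_incoming_tips(self) -> list[tuple[int, Orient]]:
        """Oriented unitigs with no predecessor (path start points)."""
        tips = []
        for uid in sorted(self.unitig_ids):
            for orient in ("+", "-"):
                if not self.predecessors(uid, orient):
                    tips.append((uid, orient))
        return tips

    @property
    def incoming_tips(self) -> set[int]:
        return {u for u, _ in self.oriented_incoming_tips()}

    @property
    def outgoing_tips(self) -> set[int]:
        out = set()
        for uid in self.unitig_ids:
            for orient in ("+", "-"):
                if not self.successors(uid, orient):
                    out.add(uid)
        return out

    def seed_unitigs(self) -> set[int]:
        return {
            self.ug.kmer_to_unitig[c]
            for c in self.seed_kmers
            if c in self.ug.kmer_to_unitig
        }


@dataclass
class CandidateTranscript:
    """A tip-to-tip simple path rendered as a nucleotide sequence."""

    sequence: str
    unitig_path: tuple[tuple[int, Orient], ...]
    source_sample: str = ""
    seed: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def extract_seed_subgraphs(
    ug: UnitigGraph, seeds: Sequence[SeedRegion]
) -> list[SeedSubgraph]:
    """Connected components (undirected reachability over end links) that
    contain at least one seed k-mer.

    A component hit by several seeds is returned once with every matching seed
    name attached; seeds with no k-mer in the graph are logged and skipped.
    """
    k = ug.params.k
    seed_hits: dict[str, set[int]] = {}
    seed_kmer_sets: dict[str, set[str]] = {}
    for seed in seeds:
        kset = seed.kmers(k)
        seed_kmer_sets[seed.name] = kset
        hits = {ug.kmer_to_unitig[c] for c in kset if c in ug.kmer_to_unitig}
        if not hits:
            logger.info("seed %s has no k-mer in the graph", seed.name)
            continue
        seed_hits[seed.name] = hits

    # undirected components over unitigs, via iterative DFS on links
    comp_of: dict[int, int] = {}
    comp_id = 0
    for start in sorted(ug.unitigs):
        if start in comp_of:
            continue
        stack = [start]
        comp_of[start] = comp_id
        while stack:
            cur = stack.pop()
            nbrs = set()
            for orient in ("+", "-"):
                nbrs |= {v for v, _ in ug.successors(cur, orient)}
            for v in nbrs:
                if v not in comp_of:
                    comp_of[v] = comp_id
                    stack.append(v)
        comp_id += 1

    by_comp: dict[int, list[str]] = {}
    for name, hits in seed_hits.items():
        for cid in {comp_of[u] for u in hits}:
            by_comp.setdefault(cid, []).append(name)

    out = []
    for cid in sorted(by_comp):
        names = sorted(by_comp[cid])
        members = {u for u, c in comp_of.items() if c == cid}
        kmers = set()
        for name in names:
            kmers |= {
                c
                for c in seed_kmer_sets[name]
                if ug.kmer_to_unitig.get(c) in members
            }
        out.append(SeedSubgraph(ug, members, names, kmers))
    return out


def prune_tips(
    sub: SeedSubgraph, min_kmers: int = 47, iterate: bool = True
) -> SeedSubgraph:
    """Remove tips shorter than ``min_kmers`` k-mers (strict: a 47-k-mer tip
    survives at the default threshold, a 46-k-mer tip does not).

    A tip is a unitig one of whose ends has no link within the subgraph.
    Unitigs containing seed k-mers are never removed.  By default pruning
    repeats until no removable tip remains, since removing a tip can expose a
    new short tip; a single pass is available via ``iterate=False``.
    """
    members = set(sub.unitig_ids)
    protected = sub.seed_unitigs()
    view = SeedSubgraph(sub.ug, members, sub.seed_names, sub.seed_kmers)
    n_removed = 0
    while True:
        removable = []
        for uid in sorted(members):
            if uid in protected:
                continue
            u = sub.ug.unitigs[uid]
            if u.kmer_count >= min_kmers:
                continue
            is_tip = not view.predecessors(uid, "+") or not view.successors(uid, "+")
            if is_tip:
                removable.append(uid)
        if not removable:
            break
        members -= set(removable)
        n_removed += len(removable)
        if not members:
            raise RuntimeError(
                f"tip pruning emptied the subgraph for seeds {sub.seed_names}"
            )
        view = SeedSubgraph(sub.ug, members, sub.seed_names, sub.seed_kmers)
        if not iterate:
            break
    if n_removed:
        logger.info(
            "pruned %d tips (<%d k-mers) from subgraph %s",
            n_removed,
            min_kmers,
            sub.seed_names,
        )
    return view


def _render_path(ug: UnitigGraph, path: Sequence[tuple[int, Orient]]) -> str:
    k = ug.params.k
    parts = []
    for i, (uid, orient) in enumerate(path):
        seq = ug.unitigs[uid].sequence
        if orient == "-":
            seq = revcomp(seq)
        parts.append(seq if i == 0 else seq[k - 1 :])
    return "".join(parts)


def enumerate_candidates(
    sub: SeedSubgraph,
    max_paths: int = 10_000,
    source_sample: str = "",
) -> list[CandidateTranscript]:
    """All simple tip-to-tip paths of the pruned subgraph, as transcripts.

    Paths are enumerated from every incoming oriented tip by depth-first
    search; a path ends whenever an oriented unitig has no successor.  Each
    candidate and its reverse complement (the same path walked from the other
    side) are reported once.  Output order is deterministic (lexicographic by
    unitig path).  Exceeding ``max_paths`` raises :class:`PathExplosionError`.
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    paths: list[tuple[tuple[int, Orient], ...]] = []
    for tip in sub.oriented_incoming_tips():
        stack: list[tuple[tuple[int, Orient], ...]] = [(tip,)]
        while stack:
            path = stack.pop()
            uid, orient = path[-1]
            succ = sorted(sub.successors(uid, orient))
            ended = True
            for v in succ:
                if any(v[0] == p[0] for p in path):
                    continue  # simple paths only: never repeat a unitig
                stack.append(path + (v,))
                ended = False
            if ended and not succ:
                paths.append(path)
                if len(paths) > 2 * max_paths:  # each path appears once per strand
                    raise PathExplosionError(
                        f"more than {max_paths} tip-to-tip paths in subgraph "
                        f"{sub.seed_names}; raise max_paths or clean the graph"
                    )

    seed_names = ",".join(sub.seed_names)
    # collapse strand duplicates: a path and its reversed flipped path render
    # to reverse-complement sequences
    best: dict[str, tuple[tuple[tuple[int, Orient], ...], str]] = {}
    for path in paths:
        seq = _render_path(sub.ug, path)
        canon = min(seq, revcomp(seq))
        if canon not in best or path < best[canon][0]:
            best[canon] = (path, seq)
    if len(best) > max_paths:
        raise PathExplosionError(
            f"{len(best)} tip-to-tip paths exceed the cap of {max_paths} "
            f"in subgraph {sub.seed_names}"
        )

    out = []
    for canon in best:
        path, seq = best[canon]
        out.append(
            CandidateTranscript(
                sequence=seq,
                unitig_path=path,
                source_sample=source_sample,
                seed=seed_names,
            )
        )
    out.sort(key=lambda c: c.unitig_path)
    return out


def orient_to_seed(
    candidates: Iterable[CandidateTranscript], seed: SeedRegion
) -> list[CandidateTranscript]:
    """Report each candidate in the orientation containing the seed sequence
    forward; candidates containing neither orientation are reported in
    canonical (lexicographically smaller) orientation."""
    out = []
    for c in candidates:
        seq = c.sequence
        path = c.unitig_path
        if seed.sequence in seq:
            pass
        elif seed.sequence in revcomp(seq):
            seq = revcomp(seq)
            path = tuple((u, _flip(o)) for u, o in reversed(path))
        elif revcomp(seq) < seq:
            seq = revcomp(seq)
            path = tuple((u, _flip(o)) for u, o in reversed(path))
        out.append(CandidateTranscript(seq, path, c.source_sample, c.seed))
    return out


def dedupe_candidates(
    candidate_sets: Mapping[str, Sequence[CandidateTranscript]],
) -> list[tuple[CandidateTranscript, list[str]]]:
    """Cross-sample aggregation keeping a single copy of duplicates.

    Two candidates are duplicates when their sequences are equal or reverse
    complements of each other; the retained representative carries the
    lexicographically smaller of (sequence, reverse complement).  Returns
    ``(representative, sorted sample names)`` pairs in deterministic order.
    """
    if not candidate_sets:
        raise ValueError("need at least one sample")
    merged: dict[str, tuple[CandidateTranscript, set[str]]] = {}
    for sample in sorted(candidate_sets):
        for c in candidate_sets[sample]:
            canon = min(c.sequence, revcomp(c.sequence))
            if canon not in merged:
                rep = CandidateTranscript(canon, c.unitig_path, sample, c.seed)
                merged[canon] = (rep, {sample})
            else:
                merged[canon][1].add(sample)
    return [
        (rep, sorted(samples)) for rep, samples in (merged[c] for c in sorted(merged))
    ]
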