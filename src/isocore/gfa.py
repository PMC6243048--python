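"""GFA1 export of unitig graphs (visualization / interchange).

S-lines carry unitig sequences with per-color mean coverage as ``cv:Z`` tags
(``color=value`` pairs, comma separated) and the k-mer count as ``km:i``.
L-lines carry end links with the overlap written as ``(k-1)M``; links are
emitted once per color with the color in a ``cl:Z`` tag.
"""

from __future__ import annotations

import io

from .graph import ColoredDBG, GraphParams
from .unitigs import Unitig, UnitigGraph


def export_gfa(ug: UnitigGraph) -> str:
    out = io.StringIO()
    k = ug.params.k
    out.write(f"H\tVN:Z:1.0\tkk:i:{k}\n")
    for uid in sorted(ug.unitigs):
        u = ug.unitigs[uid]
        cov = ",".join(
            f"{c}={u.mean_coverage.get(c, 0.0):.6g}" for c in ug.colors
        )
        out.write(f"S\t{uid}\t{u.sequence}\tkm:i:{u.kmer_count}\tcv:Z:{cov}\n")
    seen: set[tuple] = set()
    for color in ug.colors:
        adj = ug.links.get(color, {})
        for (uid, uo) in sorted(adj):
            for vid, vo in sorted(adj[(uid, uo)]):
                key = (color, uid, uo, vid, vo)
                # a link and its reverse complement are the same record
                rkey = (color, vid, "-" if vo == "+" else "+", uid, "-" if uo == "+" else "+")
                if key in seen or rkey in seen:
                    continue
                seen.add(key)
                out.write(f"L\t{uid}\t{uo}\t{vid}\t{vo}\t{k - 1}M\tcl:Z:{color}\n")
    return out.getvalue()


def parse_gfa(text: str, params: GraphParams | None = None) -> UnitigGraph:
    """Read back a graph written by :func:`export_gfa`.

    The returned graph carries unitig sequences, coverages and links; the
    underlying k-mer graph is reconstructed from the unitig sequences so that
    round-tripping preserves the unitig decomposition.
    """
    k = params.k if params else None
    header_colors: list[str] = []
    s_lines: list[tuple[int, str, int, dict[str, float]]] = []
    l_lines: list[tuple[str, int, str, int, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            for f in fields[1:]:
                if f.startswith("kk:i:"):
                    k = int(f[5:])
        elif tag == "S":
            try:
                uid = int(fields[1])
                seq = fields[2]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed S-line at line {lineno}") from exc
            km = None
            cov: dict[str, float] = {}
            for f in fields[3:]:
                if f.startswith("km:i:"):
                    km = int(f[5:])
                elif f.startswith("cv:Z:") and f[5:]:
                    for pair in f[5:].split(","):
                        name, _, val = pair.partition("=")
                        cov[name] = float(val)
            s_lines.append((uid, seq, km if km is not None else 0, cov))
            for name in cov:
                if name not in header_colors:
                    header_colors.append(name)
        elif tag == "L":
            try:
                u, uo, v, vo = int(fields[1]), fields[2], int(fields[3]), fields[4]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed L-line at line {lineno}") from exc
            color = ""
            for f in fields[6:]:
                if f.startswith("cl:Z:"):
                    color = f[5:]
            l_lines.append((color, u, uo, v, vo))
    if k is None:
        raise ValueError("GFA header lacks the k-mer length tag kk:i")
    p = params or GraphParams(k=k)
    dbg = ColoredDBG(p, header_colors)
    ug = UnitigGraph(dbg)
    for uid, seq, km, cov in s_lines:
        kmers = []
        from .dna import canonicalize

        for i in range(len(seq) - k + 1):
            kmers.append(canonicalize(seq[i : i + k])[0])
        ug.unitigs[uid] = Unitig(uid, seq, kmers, cov)
        for c in kmers:
            ug.kmer_to_unitig[c] = uid
    for color, u, uo, v, vo in l_lines:
        ug._add_link(color, (u, uo), (v, vo))
    return ug
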