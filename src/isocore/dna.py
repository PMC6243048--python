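"""Nucleotide-string primitives shared across the package.

The graph is strand-symmetric: every k-mer is stored under its canonical
form, the lexicographic minimum of the k-mer and its reverse complement.
k is restricted to odd lengths so no k-mer can equal its own reverse
complement.
"""

from __future__ import annotations

from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: bases accepted by the graph; any window containing anything else is skipped
ALPHABET = frozenset("ACGT")

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (ACGT upper case in, upper case out)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> tuple[str, bool]:
    """Return ``(canonical, flipped)`` for a k-mer.

    ``canonical`` is ``min(kmer, revcomp(kmer))``; ``flipped`` is True iff the
    reverse complement was returned.  Raises ``ValueError`` on non-ACGT input
    (callers that stream read windows skip such k-mers instead).
    """
    if not ALPHABET.issuperset(kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(kmer)
    if rc < kmer:
        return rc, True
    return kmer, False


def iter_valid_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield ``(position, kmer)`` for every length-k window over {A,C,G,T}.

    Windows containing any other symbol (N, lower case is first upper-cased)
    contribute nothing.
    """
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    # track the most recent invalid position to skip windows cheaply
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield i - k + 1, seq[i - k + 1 : i + 1]
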