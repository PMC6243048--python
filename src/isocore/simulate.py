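"""Synthetic gene models with mutually exclusive exons, and read simulation.

The generator emulates the structure of the DAL19 locus: two alternative 5'
exons (alpha, beta), a shared core region (psi), and two alternative 3' exons
(gamma, delta), giving four long isoforms (a diamond in unitig space) plus two
short core-only isoforms.  Exon sequences are uniform random over ACGT with
rejection until no two exons share a k-mer, so the diamond topology of the
graph is exact.  Short-read simulation follows a shotgun fragment model at
2x125 bp defaults; long-read (CCS) simulation produces full-length isoform
copies with optional indel errors and 5' truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dna import canonicalize, iter_valid_kmers, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: exon layout of the default diamond locus (name -> role)
FIVE_PRIME = ("alpha", "beta")
CORE = "psi"
THREE_PRIME = ("gamma", "delta")

DEFAULT_EXON_LENGTHS = {
    "alpha": 200,
    "beta": 200,
    "psi": 500,
    "gamma": 250,
    "delta": 300,
}


@dataclass
class GeneModel:
    """A synthetic locus with mutually exclusive first and last exons.

    ``exons`` are the reference exon bodies; ``flanks`` hold UTR-like margins
    attached outside the alternative first/last exons when transcribing.
    Cloned reference isoforms are exon-only, while the transcribed (and hence
    sequenced and assembled) molecules carry the flanks — which is why a
    correctly assembled path aligns to its reference with soft-clipped
    overhangs and full reference coverage.
    """

    exons: dict[str, str]
    k: int
    seed: int
    flanks: dict[str, str] = field(default_factory=dict)

    def isoform(self, five_prime: str | None, three_prime: str) -> str:
        return splice_isoform(self, five_prime, three_prime)

    def long_isoforms(self) -> dict[str, str]:
        """The four full-length reference isoforms (alternate 5' x 3')."""
        return {
            f"{f}-{CORE}-{t}": self.isoform(f, t)
            for f in FIVE_PRIME
            for t in THREE_PRIME
        }

    def short_isoforms(self) -> dict[str, str]:
        """The two core-only reference isoforms lacking an alternative 5' exon."""
        return {f"{CORE}-{t}": self.isoform(None, t) for t in THREE_PRIME}

    def transcribed(self, five_prime: str | None, three_prime: str) -> str:
        """Isoform with UTR-like flanks, as the sequenced molecule."""
        body = splice_isoform(self, five_prime, three_prime)
        left = self.flanks.get(f"utr5_{five_prime}", "") if five_prime else ""
        right = self.flanks.get(f"utr3_{three_prime}", "")
        return left + body + right

    def transcribed_isoforms(self) -> dict[str, str]:
        """The four long isoforms as transcribed molecules (with flanks)."""
        return {
            f"{f}-{CORE}-{t}": self.transcribed(f, t)
            for f in FIVE_PRIME
            for t in THREE_PRIME
        }


@dataclass(frozen=True)
class ReadSimParams:
    """Short-read library model (defaults emulate a 2x125 bp paired library)."""

    read_length: int = 125
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    substitution_rate: float = 0.0
    coverage: float = 20.0
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0,1]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_mutually_exclusive_gene(
    exon_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
    k: int = 47,
    max_tries: int = 50,
    utr_length: int = 100,
) -> GeneModel:
    """Random exon sequences, no k-mer shared between any two exons.

    ``utr_length`` controls the UTR-like flanks drawn outside each alternative
    first/last exon (also k-mer-disjoint from everything else); set it to 0
    for bare exon models.  Deterministic given ``seed``.  Raises if the
    exclusion constraint cannot be satisfied (vanishingly unlikely at
    realistic exon lengths).
    """
    lengths = dict(exon_lengths or DEFAULT_EXON_LENGTHS)
    for name, L in lengths.items():
        if L < k:
            raise ValueError(f"exon {name} shorter than k={k}")
    if utr_length:
        for f in FIVE_PRIME:
            lengths[f"utr5_{f}"] = utr_length
        for t in THREE_PRIME:
            lengths[f"utr3_{t}"] = utr_length
    rng = np.random.default_rng(seed)
    exons: dict[str, str] = {}
    used: set[str] = set()
    for name in lengths:  # insertion order: deterministic
        for _ in range(max_tries):
            seq = _random_seq(rng, lengths[name])
            kset = {canonicalize(km)[0] for _, km in iter_valid_kmers(seq, k)}
            if kset.isdisjoint(used):
                exons[name] = seq
                used |= kset
                break
        else:
            raise RuntimeError(
                f"could not draw exon {name} without a shared {k}-mer"
            )
    flanks = {n: exons.pop(n) for n in list(exons) if n.startswith("utr")}
    return GeneModel(exons, k, seed, flanks)


def splice_isoform(
    model: GeneModel, five_prime: str | None, three_prime: str
) -> str:
    """Concatenate chosen exons in genomic order; ``five_prime=None`` gives a
    short core-only isoform."""
    parts = []
    if five_prime is not None:
        if five_prime not in FIVE_PRIME or five_prime not in model.exons:
            raise KeyError(f"invalid 5' exon {five_prime!r}")
        parts.append(model.exons[five_prime])
    parts.append(model.exons[CORE])
    if three_prime not in THREE_PRIME or three_prime not in model.exons:
        raise KeyError(f"invalid 3' exon {three_prime!r}")
    parts.append(model.exons[three_prime])
    return "".join(parts)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_read_pairs(
    isoforms: Mapping[str, str],
    abundances: Mapping[str, float],
    params: ReadSimParams = ReadSimParams(),
) -> tuple[list[tuple[str, str]], list[str]]:
    """Shotgun paired reads with a truth table.

    Fragments are drawn per isoform in numbers proportional to
    abundance x length (length-weighted sampling, as in a shotgun library);
    mate 1 is the fragment's 5' end, mate 2 the reverse complement of its 3'
    end.  Substitution errors apply at ``params.substitution_rate``.  Returns
    ``(pairs, truth)`` where ``truth[i]`` names the isoform of pair ``i``.
    The target ``coverage`` is the mean per-base depth of an isoform with
    abundance weight 1.
    """
    if not isoforms:
        raise ValueError("no isoforms")
    if all(abundances.get(n, 0) <= 0 for n in isoforms):
        raise ValueError("all abundances are zero")
    rng = np.random.default_rng(params.seed)
    pairs: list[tuple[str, str]] = []
    truth: list[str] = []
    rl = params.read_length
    for name in sorted(isoforms):
        w = abundances.get(name, 0.0)
        if w <= 0:
            continue
        L = len(isoforms[name])
        n_frags = int(round(params.coverage * w * L / (2 * rl)))
        seq = isoforms[name]
        made = 0
        attempts = 0
        while made < n_frags:
            attempts += 1
            if attempts > 20 * n_frags + 100:
                logger.warning("resampling budget exhausted for %s", name)
                break
            flen = int(round(rng.normal(params.fragment_mean, params.fragment_sd)))
            flen = max(rl, flen)
            if flen > L:
                continue  # fragment longer than isoform: resample
            start = int(rng.integers(0, L - flen + 1))
            frag = seq[start : start + flen]
            m1 = _mutate(rng, frag[:rl], params.substitution_rate)
            m2 = _mutate(rng, revcomp(frag[-rl:]), params.substitution_rate)
            if params.paired:
                pairs.append((m1, m2))
            else:
                pairs.append((m1,))
            truth.append(name)
            made += 1
    return pairs, truth


def _indel_mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if r >= rate / 2 and r < rate:
            out.append(str(_BASES[rng.integers(0, 4)]))  # insertion
    return "".join(out)


def simulate_ccs_reads(
    isoforms: Mapping[str, str],
    counts: Mapping[str, int],
    indel_rate: float = 0.0,
    seed: int = 0,
    truncate_5prime_max: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Full-length long-read copies of isoforms with optional indel noise.

    ``truncate_5prime_max > 0`` trims a uniform 0..max number of 5' bases from
    each read, emulating the 5'-end loss seen in long-read cDNA libraries.
    Returns ``(reads, truth)`` keyed by read id.
    """
    rng = np.random.default_rng(seed)
    reads: dict[str, str] = {}
    truth: dict[str, str] = {}
    for name in sorted(isoforms):
        for i in range(counts.get(name, 0)):
            seq = isoforms[name]
            if truncate_5prime_max > 0:
                cut = int(rng.integers(0, truncate_5prime_max + 1))
                seq = seq[cut:]
            seq = _indel_mutate(rng, seq, indel_rate)
            rid = f"ccs_{name}_{i}"
            reads[rid] = seq
            truth[rid] = name
    return reads, truth
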