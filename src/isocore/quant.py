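"""Pseudoalignment, EM abundance estimation, and bootstrap support filtering.

Candidate transcripts enumerated from the graph include every tip-to-tip path,
expressed or not, so read support decides which survive: read pairs are
pseudoaligned to the candidate set (a pair is compatible with the transcripts
containing all of its indexed k-mers, on either strand), grouped into
equivalence classes, and allocated to transcripts by EM.  The class counts are
then resampled ``n_bootstrap`` times; a candidate is retained when its
estimated count reaches ``min_count`` in at least ``min_support_samples``
replicates (defaults 1 and 95 of 100, both inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dna import canonicalize, iter_valid_kmers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Support-filter configuration.

    ``min_count`` and ``min_support_samples`` are both inclusive thresholds;
    ``fragment_mean`` feeds the effective-length model
    ``l_eff = max(1, L - fragment_mean + 1)`` (set
    ``use_effective_length=False`` for plain lengths).
    """

    n_bootstrap: int = 100
    min_count: float = 1.0
    min_support_samples: int = 95
    em_tolerance: float = 1e-8
    em_max_iter: int = 1000
    rng_seed: int = 0
    fragment_mean: float = 200.0
    use_effective_length: bool = True
    require_both_mates_indexed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_support_samples <= self.n_bootstrap):
            raise ValueError("min_support_samples must lie in [0, n_bootstrap]")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


@dataclass
class EquivalenceClassCounts:
    """Read-pair counts grouped by compatible-transcript set."""

    classes: list[tuple[frozenset[str], int]]
    total_reads: int
    unassigned: int = 0

    def __post_init__(self) -> None:
        assert all(s and n >= 1 for s, n in self.classes)
        assert sum(n for _, n in self.classes) == self.total_reads


@dataclass
class AbundanceEstimate:
    counts: dict[str, float]
    effective_lengths: dict[str, float]
    converged: bool
    n_iter: int


@dataclass
class BootstrapSupport:
    """Per-transcript number of bootstrap replicates meeting the count rule."""

    support: dict[str, int]
    n_bootstrap: int
    point_estimate: AbundanceEstimate | None = None


class PseudoIndex:
    """k-mer -> transcript-set index over a candidate collection."""

    def __init__(self, candidates: Mapping[str, str], k: int) -> None:
        self.k = k
        self.transcripts = dict(candidates)
        self.kmer_to_tx: dict[str, set[str]] = {}
        for tx_id, seq in candidates.items():
            for _, km in iter_valid_kmers(seq, k):
                canon, _ = canonicalize(km)
                self.kmer_to_tx.setdefault(canon, set()).add(tx_id)

    def lengths(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.transcripts.items()}


def pseudoalign_pair(
    pair: tuple[str, str] | tuple[str], index: PseudoIndex
) -> frozenset[str]:
    """Compatibility set of a (single- or paired-end) read.

    The intersection over all *indexed* k-mers of both mates of the transcript
    sets containing each k-mer; k-mers absent from every candidate are skipped
    rather than forcing emptiness, and a pair with no indexed k-mer at all is
    unassigned (empty set).
    """
    result: set[str] | None = None
    for mate in pair:
        for _, km in iter_valid_kmers(mate, index.k):
            canon, _ = canonicalize(km)
            txs = index.kmer_to_tx.get(canon)
            if txs is None:
                continue
            if result is None:
                result = set(txs)
            else:
                result &= txs
            if not result:
                return frozenset()
    return frozenset(result) if result else frozenset()


def _mate_indexed(mate: str, index: PseudoIndex) -> bool:
    return any(
        canonicalize(km)[0] in index.kmer_to_tx
        for _, km in iter_valid_kmers(mate, index.k)
    )


def build_ec_counts(
    pairs: Iterable[tuple[str, str]],
    index: PseudoIndex,
    require_both_mates_indexed: bool = False,
) -> EquivalenceClassCounts:
    """Group read pairs into equivalence classes by pseudoalignment set.

    ``require_both_mates_indexed`` is an internal stand-in for the original
    pipeline's external pre-mapping step ("both reads mapped"): a pair whose
    either mate shares no k-mer with any candidate is dropped up front.
    Unassigned pairs are excluded from the classes and tallied separately.
    """
    tally: dict[frozenset[str], int] = {}
    unassigned = 0
    for pair in pairs:
        if require_both_mates_indexed and not all(
            _mate_indexed(m, index) for m in pair
        ):
            unassigned += 1
            continue
        s = pseudoalign_pair(pair, index)
        if not s:
            unassigned += 1
            continue
        tally[s] = tally.get(s, 0) + 1
    classes = sorted(tally.items(), key=lambda kv: sorted(kv[0]))
    total = sum(tally.values())
    if unassigned:
        logger.info("%d read pairs unassigned during pseudoalignment", unassigned)
    return EquivalenceClassCounts(classes, total, unassigned)


def effective_lengths(
    lengths: Mapping[str, float], params: FilterParams
) -> dict[str, float]:
    if not params.use_effective_length:
        return {t: float(L) for t, L in lengths.items()}
    return {t: max(1.0, L - params.fragment_mean + 1.0) for t, L in lengths.items()}


def _em(
    class_members: list[np.ndarray],
    class_counts: np.ndarray,
    eff_len: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool, int]:
    """EM on equivalence-class counts.

    E-step allocates each class count across its members proportional to
    theta/l_eff; M-step renormalizes theta from allocations.  Returns the
    final allocated counts (summing to the class total), convergence flag and
    iteration count.
    """
    n_tx = len(eff_len)
    total = class_counts.sum()
    theta = np.full(n_tx, 1.0 / n_tx)
    alloc = np.zeros(n_tx)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alloc[:] = 0.0
        for members, count in zip(class_members, class_counts):
            w = theta[members] / eff_len[members]
            wsum = w.sum()
            if wsum <= 0:
                w = np.full(len(members), 1.0 / len(members))
                wsum = 1.0
            alloc[members] += count * (w / wsum)
        new_theta = alloc / total if total > 0 else theta
        denom = np.where(theta > 0, theta, 1.0)
        delta = np.abs(new_theta - theta) / denom
        theta = new_theta
        if delta.max() < tol:
            converged = True
            break
    return alloc, converged, it


def em_abundance(
    ec: EquivalenceClassCounts,
    lengths: Mapping[str, float],
    params: FilterParams = FilterParams(),
    transcripts: Sequence[str] | None = None,
) -> AbundanceEstimate:
    """Maximum-likelihood allocation of class counts to transcripts.

    Estimated counts are post-EM allocated read counts (not TPM) and sum to
    ``ec.total_reads``.  Transcripts appearing in no class get count 0.
    """
    if transcripts is None:
        txs = sorted(lengths)
    else:
        txs = list(transcripts)
    for s, _ in ec.classes:
        for t in s:
            if t not in lengths:
                raise KeyError(f"transcript {t} has no length")
    idx = {t: i for i, t in enumerate(txs)}
    eff = effective_lengths(lengths, params)
    eff_arr = np.array([eff[t] for t in txs])
    members = [
        np.array(sorted(idx[t] for t in s), dtype=int) for s, _ in ec.classes
    ]
    counts = np.array([n for _, n in ec.classes], dtype=float)
    if not ec.classes:
        return AbundanceEstimate({t: 0.0 for t in txs}, eff, True, 0)
    alloc, converged, n_iter = _em(
        members, counts, eff_arr, params.em_tolerance, params.em_max_iter
    )
    if not converged:
        logger.warning("EM did not converge in %d iterations", params.em_max_iter)
    return AbundanceEstimate(
        {t: float(alloc[idx[t]]) for t in txs}, eff, converged, n_iter
    )


def bootstrap_support(
    ec: EquivalenceClassCounts,
    lengths: Mapping[str, float],
    params: FilterParams = FilterParams(),
) -> BootstrapSupport:
    """Resample class counts multinomially and re-run EM per replicate.

    Resampling acts on equivalence-class counts rather than raw reads — the
    resampling distribution is identical and the cost is proportional to the
    number of classes, not reads.  Deterministic given ``params.rng_seed``.
    """
    txs = sorted(lengths)
    point = em_abundance(ec, lengths, params, txs)
    support = {t: 0 for t in txs}
    if ec.total_reads == 0:
        return BootstrapSupport(support, params.n_bootstrap, point)
    rng = np.random.default_rng(params.rng_seed)
    idx = {t: i for i, t in enumerate(txs)}
    eff = effective_lengths(lengths, params)
    eff_arr = np.array([eff[t] for t in txs])
    members = [np.array(sorted(idx[t] for t in s), dtype=int) for s, _ in ec.classes]
    counts = np.array([n for _, n in ec.classes], dtype=float)
    probs = counts / counts.sum()
    draws = rng.multinomial(ec.total_reads, probs, size=params.n_bootstrap)
    for rep in range(params.n_bootstrap):
        c = draws[rep].astype(float)
        nz = c > 0
        alloc, _, _ = _em(
            [m for m, keep in zip(members, nz) if keep],
            c[nz],
            eff_arr,
            params.em_tolerance,
            params.em_max_iter,
        )
        for t, i in idx.items():
            if alloc[i] >= params.min_count:
                support[t] += 1
    return BootstrapSupport(support, params.n_bootstrap, point)


def retain_candidates(
    support: BootstrapSupport, params: FilterParams = FilterParams()
) -> set[str]:
    """Transcripts whose support meets ``min_support_samples`` (inclusive)."""
    return {
        t for t, s in support.support.items() if s >= params.min_support_samples
    }
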