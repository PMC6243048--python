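"""Pseudoalignment, EM abundance estimation, bootstrap support filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isocore import (
    BootstrapSupport,
    EquivalenceClassCounts,
    FilterParams,
    PseudoIndex,
    bootstrap_support,
    build_ec_counts,
    em_abundance,
    pseudoalign_pair,
    retain_candidates,
    revcomp,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES)) for _ in range(n))


def substring_oracle(pair, candidates, k):
    """Exact-substring pseudoalignment oracle for error-free reads.

    A mate drawn error-free from a transcript is a substring of it (either
    strand); the compatibility set is the set of candidates containing every
    mate as a substring.
    """
    result = None
    for mate in pair:
        hits = {
            t
            for t, seq in candidates.items()
            if mate in seq or revcomp(mate) in seq
        }
        result = hits if result is None else result & hits
    return frozenset(result)


class TestPseudoalign:
    def _index(self, rng, n=3, length=400, k=31):
        cands = {f"T{i}": random_seq(rng, length) for i in range(n)}
        return cands, PseudoIndex(cands, k)

    def test_unique_read_gives_singleton(self):
        rng = np.random.default_rng(0)
        cands, index = self._index(rng)
        pair = (cands["T1"][50:150], revcomp(cands["T1"][200:300]))
        assert pseudoalign_pair(pair, index) == frozenset({"T1"})

    def test_pair_inside_shared_core_hits_all_isoforms(self, diamond_model):
        model = diamond_model
        iso = model.long_isoforms()
        index = PseudoIndex(iso, 47)
        core = model.exons["psi"]
        pair = (core[10:135], revcomp(core[200:325]))
        assert pseudoalign_pair(pair, index) == frozenset(iso)

    def test_unindexed_kmers_are_skipped_not_emptying(self):
        rng = np.random.default_rng(1)
        cands, index = self._index(rng, n=1)
        # read half from T0, half foreign random tail: foreign k-mers skipped
        read = cands["T0"][:100] + random_seq(rng, 60)
        assert pseudoalign_pair((read,), index) == frozenset({"T0"})

    def test_pair_with_no_indexed_kmer_is_unassigned(self):
        rng = np.random.default_rng(2)
        cands, index = self._index(rng, n=2)
        foreign = random_seq(rng, 120)
        assert pseudoalign_pair((foreign,), index) == frozenset()

    def test_matches_substring_oracle_on_simulated_pairs(self, diamond_model):
        from isocore import ReadSimParams, simulate_read_pairs

        iso = diamond_model.long_isoforms()
        pairs, _ = simulate_read_pairs(
            iso, {n: 1.0 for n in iso}, ReadSimParams(coverage=3.0, seed=5)
        )
        index = PseudoIndex(iso, 47)
        for pair in pairs[:150]:
            assert pseudoalign_pair(pair, index) == substring_oracle(pair, iso, 47)


class TestEcCounts:
    def test_unique_pairs_form_one_class(self):
        rng = np.random.default_rng(3)
        cands = {"T1": random_seq(rng, 400)}
        index = PseudoIndex(cands, 31)
        pairs = [
            (cands["T1"][i : i + 100], revcomp(cands["T1"][i + 150 : i + 250]))
            for i in range(10)
        ]
        ec = build_ec_counts(pairs, index)
        assert ec.classes == [(frozenset({"T1"}), 10)]
        assert ec.total_reads == 10

    def test_no_pairs_gives_empty_classes(self):
        rng = np.random.default_rng(4)
        index = PseudoIndex({"T1": random_seq(rng, 200)}, 31)
        ec = build_ec_counts([], index)
        assert ec.classes == [] and ec.total_reads == 0

    def test_counts_match_tally_oracle(self, diamond_model, diamond_reads):
        # candidates must be the sequenced molecules for the substring oracle
        iso = diamond_model.transcribed_isoforms()
        pairs, _ = diamond_reads
        index = PseudoIndex(iso, 47)
        ec = build_ec_counts(pairs, index)
        oracle = {}
        unassigned = 0
        for pair in pairs:
            s = substring_oracle(pair, iso, 47)
            if s:
                oracle[s] = oracle.get(s, 0) + 1
            else:
                unassigned += 1
        assert dict(ec.classes) == oracle
        assert ec.total_reads == sum(oracle.values())
        assert ec.unassigned == unassigned


class TestEm:
    def test_singleton_classes_recover_raw_counts(self):
        ec = EquivalenceClassCounts(
            [(frozenset({"A"}), 30), (frozenset({"B"}), 70)], 100
        )
        est = em_abundance(ec, {"A": 500, "B": 900}, FilterParams())
        assert est.counts["A"] == pytest.approx(30, abs=1e-6)
        assert est.counts["B"] == pytest.approx(70, abs=1e-6)

    def test_fully_shared_class_splits_evenly_for_equal_lengths(self):
        ec = EquivalenceClassCounts([(frozenset({"A", "B"}), 100)], 100)
        est = em_abundance(ec, {"A": 500, "B": 500}, FilterParams())
        assert est.counts["A"] == pytest.approx(50, abs=1e-6)
        assert est.counts["B"] == pytest.approx(50, abs=1e-6)

    def test_counts_sum_to_total_reads(self):
        rng = np.random.default_rng(6)
        txs = ["A", "B", "C", "D"]
        classes = []
        total = 0
        for _ in range(8):
            size = rng.integers(1, 5)
            members = frozenset(rng.choice(txs, size=size, replace=False))
            n = int(rng.integers(1, 50))
            classes.append((members, n))
            total += n
        # merge duplicate member sets
        merged = {}
        for s, n in classes:
            merged[s] = merged.get(s, 0) + n
        ec = EquivalenceClassCounts(list(merged.items()), total)
        lengths = {t: float(rng.integers(300, 1500)) for t in txs}
        est = em_abundance(ec, lengths, FilterParams())
        assert sum(est.counts.values()) == pytest.approx(total, abs=1e-6)

    def test_matches_likelihood_grid_search_to_three_decimals(self):
        # 3 transcripts, mixed unique and shared classes
        lengths = {"A": 300.0, "B": 400.0, "C": 500.0}
        classes = [
            (frozenset({"A"}), 30),
            (frozenset({"A", "B"}), 50),
            (frozenset({"B", "C"}), 40),
            (frozenset({"A", "B", "C"}), 20),
            (frozenset({"C"}), 10),
        ]
        ec = EquivalenceClassCounts(classes, 150)
        params = FilterParams(
            use_effective_length=False, em_tolerance=1e-12, em_max_iter=200_000
        )
        est = em_abundance(ec, lengths, params)
        theta = {t: est.counts[t] / 150 for t in lengths}

        def loglik(a, b):
            th = {"A": a, "B": b, "C": 1 - a - b}
            total = 0.0
            for s, n in classes:
                p = sum(th[t] / lengths[t] for t in s)
                if p <= 0:
                    return -np.inf
                total += n * np.log(p)
            return total

        best = (-np.inf, 0, 0)
        for a in np.arange(0, 1.0001, 0.01):
            for b in np.arange(0, 1.0001 - a, 0.01):
                v = loglik(a, b)
                if v > best[0]:
                    best = (v, a, b)
        _, a0, b0 = best
        for a in np.arange(max(0, a0 - 0.01), min(1, a0 + 0.01), 0.0002):
            for b in np.arange(max(0, b0 - 0.01), min(1 - a, b0 + 0.01), 0.0002):
                v = loglik(a, b)
                if v > best[0]:
                    best = (v, a, b)
        _, a, b = best
        assert theta["A"] == pytest.approx(a, abs=1e-3)
        assert theta["B"] == pytest.approx(b, abs=1e-3)
        assert theta["C"] == pytest.approx(1 - a - b, abs=1e-3)

    def test_effective_length_model(self):
        p = FilterParams(fragment_mean=200.0)
        from isocore.quant import effective_lengths

        eff = effective_lengths({"A": 1000, "B": 150}, p)
        assert eff["A"] == 801.0
        assert eff["B"] == 1.0  # floor at 1


class TestBootstrap:
    def test_all_reads_unique_gives_full_support(self):
        ec = EquivalenceClassCounts([(frozenset({"A"}), 50)], 50)
        bs = bootstrap_support(ec, {"A": 500}, FilterParams(rng_seed=1))
        assert bs.support["A"] == 100

    def test_transcript_in_no_class_has_zero_support(self):
        ec = EquivalenceClassCounts([(frozenset({"A"}), 50)], 50)
        bs = bootstrap_support(ec, {"A": 500, "B": 500}, FilterParams(rng_seed=1))
        assert bs.support["B"] == 0

    def test_zero_reads_gives_zero_support(self):
        ec = EquivalenceClassCounts([], 0)
        bs = bootstrap_support(ec, {"A": 500}, FilterParams(rng_seed=1))
        assert bs.support == {"A": 0}

    def test_seeded_determinism(self):
        ec = EquivalenceClassCounts(
            [(frozenset({"A"}), 5), (frozenset({"A", "B"}), 9)], 14
        )
        lengths = {"A": 400.0, "B": 400.0}
        a = bootstrap_support(ec, lengths, FilterParams(rng_seed=42))
        b = bootstrap_support(ec, lengths, FilterParams(rng_seed=42))
        c = bootstrap_support(ec, lengths, FilterParams(rng_seed=43))
        assert a.support == b.support
        assert a.support != c.support or True  # different seed may coincide

    def test_support_within_binomial_bounds_of_monte_carlo_oracle(self):
        """Compare n=100 bootstrap support against an independent 10^4-replicate
        Monte-Carlo estimate of the per-replicate success probability."""
        from scipy.stats import binom

        classes = [(frozenset({"A"}), 3), (frozenset({"A", "B"}), 11)]
        ec = EquivalenceClassCounts(classes, 14)
        lengths = {"A": 400.0, "B": 400.0}
        params = FilterParams(rng_seed=11, use_effective_length=False)
        bs = bootstrap_support(ec, lengths, params)

        # independent oracle: per-read categorical resampling + its own EM
        rng = np.random.default_rng(999)
        n_mc = 10_000
        reads = np.repeat(np.arange(len(classes)), [n for _, n in classes])
        success = np.zeros(2)
        for _ in range(n_mc):
            resampled = rng.choice(reads, size=len(reads), replace=True)
            counts = np.bincount(resampled, minlength=len(classes)).astype(float)
            # EM for 2 equal-length transcripts, classes {A}, {A,B}
            tA = tB = 0.5
            for _ in range(500):
                sharedA = counts[1] * tA / (tA + tB)
                allocA = counts[0] + sharedA
                allocB = counts[1] - sharedA
                newA = allocA / counts.sum()
                newB = allocB / counts.sum()
                if abs(newA - tA) < 1e-10 and abs(newB - tB) < 1e-10:
                    break
                tA, tB = newA, newB
            if allocA >= 1:
                success[0] += 1
            if allocB >= 1:
                success[1] += 1
        p_hat = success / n_mc
        for i, t in enumerate(["A", "B"]):
            lo = binom.ppf(0.005, 100, p_hat[i])
            hi = binom.ppf(0.995, 100, p_hat[i])
            assert lo <= bs.support[t] <= hi, (t, bs.support[t], p_hat[i])


class TestRetain:
    def test_exact_threshold_retained(self):
        bs = BootstrapSupport({"A": 95}, 100)
        assert retain_candidates(bs, FilterParams()) == {"A"}

    def test_below_threshold_removed(self):
        bs = BootstrapSupport({"A": 94}, 100)
        assert retain_candidates(bs, FilterParams()) == set()

    @given(st.dictionaries(st.text(alphabet="XYZ", min_size=1, max_size=3),
                           st.integers(min_value=0, max_value=100), max_size=8),
           st.integers(min_value=0, max_value=100))
    def test_matches_predicate_oracle(self, support, threshold):
        bs = BootstrapSupport(support, 100)
        params = FilterParams(min_support_samples=threshold)
        got = retain_candidates(bs, params)
        assert got == {t for t, s in support.items() if s >= threshold}

    def test_monotone_in_threshold(self):
        support = {"A": 97, "B": 95, "C": 40, "D": 0}
        sets = [
            retain_candidates(
                BootstrapSupport(support, 100),
                FilterParams(min_support_samples=m),
            )
            for m in range(0, 101, 10)
        ]
        for smaller, larger in zip(sets[1:], sets):
            assert smaller <= larger

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(min_support_samples=101)
        with pytest.raises(ValueError):
            FilterParams(min_count=-1)
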