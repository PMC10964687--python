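"""Sparse motif tree: construction, search, enrichment, diagnostics."""

import collections
import itertools

import numpy as np
import pytest

from treemotif.background import BackgroundModel
from treemotif.seqio import SequenceDataset
from treemotif.smt import (
    create_smt,
    extract_enriched,
    group_seeds,
    kdive,
    ksearch,
    occupancy,
    simulate_kdive_cost,
)
from treemotif.synthetic import PlantSpec, generate_planted

from conftest import random_dataset


def dict_counts(dataset, k):
    """Brute-force dictionary count of all N-free k-windows."""
    counts = collections.Counter()
    addrs = collections.defaultdict(list)
    for i, (_, seq) in enumerate(dataset):
        for u in range(len(seq) - k + 1):
            w = seq[u:u + k]
            if "N" not in w:
                counts[w] += 1
                addrs[w].append((i, u))
    return counts, addrs


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture
def worked_tree():
    with pytest.warns(UserWarning):
        return create_smt(SequenceDataset([("x", "ACGTACGAT")]), k=4)


class TestCreateSmt:
    def test_worked_example_six_kmers(self, worked_tree):
        # ACGTACGAT with k=4 yields six overlapping windows
        assert worked_tree.total_count() == 6

    def test_repeat_insert_increments_without_new_nodes(self):
        with pytest.warns(UserWarning):
            one = create_smt(SequenceDataset([("x", "ACGT")]), k=4)
        with pytest.warns(UserWarning):
            two = create_smt(SequenceDataset([("x", "ACGT"), ("y", "ACGT")]), k=4)
        assert one.nu == two.nu == 5
        assert ksearch(two, "ACGT")[0] == 2

    def test_empty_dataset_root_only(self):
        tree = create_smt(SequenceDataset([]), k=6)
        assert tree.nu == 1 and tree.n_terminals == 0

    def test_short_sequences_contribute_nothing(self):
        tree = create_smt(SequenceDataset([("a", "ACG"), ("b", "ACGTAC")]), k=6)
        assert tree.total_count() == 1

    def test_windows_with_n_skipped(self):
        tree = create_smt(SequenceDataset([("a", "ACGNACG")]), k=3)
        counts, _ = dict_counts(SequenceDataset([("a", "ACGNACG")]), 3)
        assert tree.total_count() == sum(counts.values()) == 2

    def test_counts_match_dictionary_oracle(self, rng):
        ds = random_dataset(rng, 50, 40)
        tree = create_smt(ds, k=6)
        counts, addrs = dict_counts(ds, 6)
        stored = {w: (c, a) for w, c, a in tree.iter_kmers()}
        assert {w: c for w, (c, _) in stored.items()} == dict(counts)
        for w, (_, a) in stored.items():
            assert sorted(a) == sorted(addrs[w])

    def test_conservation_invariant(self, rng):
        ds = random_dataset(rng, 20, 35)
        tree = create_smt(ds, k=8)
        assert tree.total_count() == sum(t - 8 + 1 for t in ds.widths)

    def test_numeric_code_decodes_path(self, rng):
        ds = random_dataset(rng, 10, 30)
        tree = create_smt(ds, k=7)
        for node, addr in tree.addresses.items():
            i, u = addr[0]
            assert tree.decode_terminal(node) == ds.sequences[i][u:u + 7]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            create_smt(SequenceDataset([("a", "ACGT")]), k=0)


class TestKsearch:
    def test_present_kmer(self, worked_tree):
        count, addrs = ksearch(worked_tree, "ACGT")
        assert count == 1 and addrs == [(0, 0)]

    def test_absent_kmer(self, worked_tree):
        assert ksearch(worked_tree, "TTTT") == (0, [])

    def test_matches_oracle_for_all_stored(self, rng):
        ds = random_dataset(rng, 15, 30)
        tree = create_smt(ds, k=5)
        counts, _ = dict_counts(ds, 5)
        for w, c in counts.items():
            assert ksearch(tree, w)[0] == c

    def test_wrong_length_raises(self, worked_tree):
        with pytest.raises(ValueError):
            ksearch(worked_tree, "ACG")


class TestKdive:
    def test_dmax0_equals_exact_search(self, rng):
        ds = random_dataset(rng, 10, 25)
        tree = create_smt(ds, k=5)
        for _ in range(50):
            q = "".join("ACGT"[c] for c in rng.integers(0, 4, 5))
            assert kdive(tree, q, 0) == (ksearch(tree, q)[0] > 0)

    def test_boolean_mode_finds_stored_kmer(self, rng):
        ds = random_dataset(rng, 5, 30)
        tree = create_smt(ds, k=10)
        stored = next(tree.iter_kmers())[0]
        assert kdive(tree, stored, 2) is True

    def test_collect_matches_hamming_ball_oracle(self, rng):
        # >= 100 randomized instances against brute-force enumeration
        for trial in range(100):
            k = int(rng.integers(4, 9))
            ds = random_dataset(rng, int(rng.integers(2, 8)), 30)
            tree = create_smt(ds, k=k)
            d = int(rng.integers(0, 3))
            q = "".join("ACGT"[c] for c in rng.integers(0, 4, k))
            got = {(m.kmer, m.distance, m.count) for m in kdive(tree, q, d, collect=True)}
            counts, _ = dict_counts(ds, k)
            want = {(w, hamming(w, q), c) for w, c in counts.items()
                    if hamming(w, q) <= d}
            assert got == want

    def test_monotone_in_dmax(self, rng):
        ds = random_dataset(rng, 10, 30)
        tree = create_smt(ds, k=6)
        q = ds.sequences[0][:6]
        for d in range(5):
            a = {m.kmer for m in kdive(tree, q, d, collect=True)}
            b = {m.kmer for m in kdive(tree, q, d + 1, collect=True)}
            assert a <= b

    def test_dmax_k_returns_everything(self, rng):
        ds = random_dataset(rng, 5, 25)
        tree = create_smt(ds, k=6)
        got = {m.kmer for m in kdive(tree, "A" * 6, 6, collect=True)}
        assert got == {w for w, _, _ in tree.iter_kmers()}

    def test_negative_dmax_raises(self, worked_tree):
        with pytest.raises(ValueError):
            kdive(worked_tree, "ACGT", -1)


class TestOccupancy:
    def test_single_kmer_path(self):
        with pytest.warns(UserWarning):
            tree = create_smt(SequenceDataset([("x", "ACGT")]), k=4)
        # 5 nodes, 4 occupied child cells
        assert occupancy(tree) == pytest.approx(4 / 20)

    def test_all_four_single_bases(self):
        with pytest.warns(UserWarning):
            tree = create_smt(SequenceDataset([("x", "ACGT")]), k=1)
        assert tree.nu == 5
        assert occupancy(tree) == pytest.approx(4 / 20)

    def test_below_analytic_half_on_uniform_data(self, rng):
        tree = create_smt(random_dataset(rng, 100, 200), k=12)
        occ = occupancy(tree)
        assert 0 < occ < 0.5


class TestKdiveCost:
    def test_deterministic_at_p_one(self):
        assert simulate_kdive_cost(d=4, p=1.0, reps=1000, seed=0) == 4.0

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("p", [0.25, 0.5, 0.75])
    def test_matches_closed_form_mean(self, d, p):
        reps = 50_000
        est = simulate_kdive_cost(d, p, reps, seed=d * 100 + int(p * 4))
        var = d * (1 - p) / p**2  # sum of d geometric variances
        se = np.sqrt(var / reps)
        assert abs(est - d / p) <= 3 * se

    def test_reproducible(self):
        a = simulate_kdive_cost(3, 0.5, 1000, seed=5)
        assert a == simulate_kdive_cost(3, 0.5, 1000, seed=5)


class TestEnrichment:
    def test_uniform_background_expected_count(self, rng, uniform_bg):
        # 10 sequences of width 20, k=5: 160 windows, expected 160/4^5
        ds = random_dataset(rng, 10, 20)
        tree = create_smt(ds, k=5)
        recs = extract_enriched(tree, uniform_bg, alpha=0.999999)
        assert recs
        for r in recs:
            assert r.expected == pytest.approx(160 * 4**-5)

    def test_planted_consensus_is_most_significant(self, uniform_bg):
        ds, truth = generate_planted(
            PlantSpec(n=60, t=40, k=8, d=0, model="oops", seed=3)
        )
        tree = create_smt(ds, k=8)
        recs = extract_enriched(tree, uniform_bg, alpha=0.01)
        assert recs[0].kmer == truth.consensus

    def test_q_nondecreasing_in_p(self, rng, uniform_bg):
        ds = random_dataset(rng, 10, 40)
        tree = create_smt(ds, k=5)
        recs = extract_enriched(tree, uniform_bg, alpha=0.999999)
        by_p = sorted(recs, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in recs)

    def test_empty_tree_empty_list(self, uniform_bg):
        tree = create_smt(SequenceDataset([]), k=6)
        assert extract_enriched(tree, uniform_bg, alpha=0.05) == []


class TestGroupSeeds:
    def _toy(self):
        # AAAA x 3 and AAAT x 2 sit at Hamming distance 1
        ds = SequenceDataset([("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA"),
                              ("d", "AAAT"), ("e", "AAAT")])
        with pytest.warns(UserWarning):
            tree = create_smt(ds, k=4)
        recs = extract_enriched(tree, BackgroundModel.uniform(), alpha=0.999999)
        return tree, recs

    def test_d0_passthrough(self):
        tree, recs = self._toy()
        assert group_seeds(tree, recs, d=0, n_seeds=2) == recs[:2]

    def test_neighbors_aggregated_into_one_seed(self):
        tree, recs = self._toy()
        seeds = group_seeds(tree, recs, d=1, n_seeds=5)
        assert len(seeds) == 1
        assert seeds[0].kmer == "AAAA" and seeds[0].observed == 5

    def test_no_double_counting_and_seeds_separated(self, rng, uniform_bg):
        ds = random_dataset(rng, 30, 30)
        tree = create_smt(ds, k=6)
        recs = extract_enriched(tree, uniform_bg, alpha=0.999999)
        seeds = group_seeds(tree, recs, d=1, n_seeds=8)
        # claimed neighborhoods are disjoint, so aggregated counts can
        # never exceed the total number of inserted windows
        assert sum(s.observed for s in seeds) <= tree.total_count()
        for a, b in itertools.combinations(seeds, 2):
            assert hamming(a.kmer, b.kmer) > 1
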