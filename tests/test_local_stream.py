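import numpy as np
import pytest

from glaret import (
    ActivationTensor,
    TransactionDB,
    binarize_feature_map,
    build_fp_tree,
    build_transactions,
    fp_growth,
    local_feature,
    mine_patterns,
    support,
)
from glaret.features import flat_index
from glaret.global_stream import full_grid_region, pool_region, Region
from glaret.local_stream import (
    MiningExplosionError,
    read_transactions,
    write_patterns,
    write_transactions,
)
from glaret.synthetic import NoiseSpec, PartPlant, SceneSpec, brute_force_patterns, generate_tensor
from conftest import random_db


def as_sets(pattern_set):
    return {(tuple(sorted(p.items)), p.support) for p in pattern_set.patterns}


class TestBinarize:
    def test_strictly_above_channel_mean(self):
        vals = np.array([[0, 2], [4, 2]], dtype=float).reshape(2, 2, 1)
        assert binarize_feature_map(ActivationTensor(vals), 0) == {flat_index(1, 0, 2)}

    def test_constant_channel_empty(self):
        assert binarize_feature_map(ActivationTensor(np.ones((3, 3, 1))), 0) == frozenset()

    def test_single_positive_cell(self):
        vals = np.zeros((3, 3, 1))
        vals[1, 2, 0] = 5.0
        assert binarize_feature_map(ActivationTensor(vals), 0) == {flat_index(1, 2, 3)}


class TestBuildTransactions:
    def test_one_transaction_per_channel(self):
        rng = np.random.default_rng(0)
        t = ActivationTensor(rng.random((3, 3, 10)))
        db = build_transactions(t)
        assert db.m == 10
        assert all(db.transactions[i].map_index == i for i in range(10))
        assert db.item_universe <= frozenset(range(9))

    def test_all_zero_tensor_empty_transactions(self):
        db = build_transactions(ActivationTensor(np.zeros((3, 3, 5))))
        assert db.m == 5
        assert db.item_universe == frozenset()

    def test_constructed_identical_transactions(self):
        # channels 0-9 exceed their means exactly at positions {1, 5}
        vals = np.zeros((3, 3, 10))
        for ch in range(10):
            vals[0, 1, ch] = 4.0  # flat 1
            vals[1, 2, ch] = 4.0  # flat 5
        db = build_transactions(ActivationTensor(vals))
        assert all(t.items == {1, 5} for t in db.transactions)


class TestSupport:
    def test_exhaustive_containment_count(self, worked_db):
        assert support({0, 1}, worked_db) == 2

    def test_empty_itemset_in_every_transaction(self, worked_db):
        assert support(set(), worked_db) == worked_db.m

    def test_absent_item(self, worked_db):
        assert support({99}, worked_db) == 0

    def test_matches_brute_count_on_random_dbs(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            db = random_db(rng)
            items = set(
                rng.choice(sorted(db.item_universe | {0}), size=min(2, 1 + len(db.item_universe)))
            )
            expected = sum(1 for t in db.transactions if items <= t.items)
            assert support(items, db) == expected


class TestFPTree:
    def test_worked_instance_structure(self, worked_db):
        tree = build_fp_tree(worked_db, minsupp=2)
        # supports a:3, b:3, c:2; tie between a and b broken by ascending id
        assert tree.item_order == [0, 1, 2]
        # three transactions start with a and share that prefix; the lone {b}
        # transaction necessarily opens a second branch under the root
        assert set(tree.root.children) == {0, 1}
        assert tree.root.children[0].count == 3
        assert tree.root.children[1].count == 1

    def test_header_chain_counts_equal_supports(self, worked_db):
        tree = build_fp_tree(worked_db, minsupp=2)
        for item, supp in tree.item_support.items():
            assert sum(node.count for node in tree.header_chain(item)) == supp

    def test_header_chain_conservation_on_random_dbs(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            db = random_db(rng)
            minsupp = int(rng.integers(1, db.m + 1))
            tree = build_fp_tree(db, minsupp)
            for item, supp in tree.item_support.items():
                assert sum(n.count for n in tree.header_chain(item)) == supp

    def test_minsupp_above_m_gives_root_only_tree(self, worked_db):
        tree = build_fp_tree(worked_db, minsupp=worked_db.m + 1)
        assert tree.root.children == {} and tree.item_order == []

    def test_single_transaction_single_path(self):
        db = TransactionDB.from_itemsets([{0, 1}])
        tree = build_fp_tree(db, minsupp=1)
        first = tree.root.children[0]
        assert first.count == 1 and list(first.children) == [1]
        assert first.children[1].count == 1


class TestFPGrowth:
    def test_worked_instance_all(self, worked_db):
        out = fp_growth(build_fp_tree(worked_db, 2), 2, mode="all")
        assert as_sets(out) == {
            ((0,), 3), ((1,), 3), ((2,), 2), ((0, 1), 2), ((0, 2), 2),
        }

    def test_worked_instance_maximal(self, worked_db):
        out = fp_growth(build_fp_tree(worked_db, 2), 2, mode="maximal")
        assert as_sets(out) == {((0, 1), 2), ((0, 2), 2)}

    def test_single_transaction_minsupp_one(self):
        db = TransactionDB.from_itemsets([{0}])
        out = fp_growth(build_fp_tree(db, 1), 1)
        assert as_sets(out) == {((0,), 1)}

    def test_oracle_equivalence_on_random_dbs(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            db = random_db(rng)
            for minsupp in range(1, db.m + 1):
                mined = fp_growth(build_fp_tree(db, minsupp), minsupp)
                oracle = brute_force_patterns(db, minsupp)
                assert as_sets(mined) == as_sets(oracle)

    def test_apriori_monotonicity(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            db = random_db(rng, max_m=8, max_n=6)
            mined = fp_growth(build_fp_tree(db, 2), 2)
            by_items = {p.items: p.support for p in mined.patterns}
            for items, supp in by_items.items():
                for drop in items:
                    sub = items - {drop}
                    if sub:
                        assert by_items[sub] >= supp

    def test_transaction_order_invariance(self):
        rng = np.random.default_rng(31)
        db = random_db(rng)
        perm = rng.permutation(db.m)
        shuffled = TransactionDB.from_itemsets([db.transactions[i].items for i in perm])
        a = fp_growth(build_fp_tree(db, 2), 2)
        b = fp_growth(build_fp_tree(shuffled, 2), 2)
        assert as_sets(a) == as_sets(b)

    def test_canonical_output_order(self, worked_db):
        out = fp_growth(build_fp_tree(worked_db, 2), 2)
        keys = [(-p.support, tuple(sorted(p.items))) for p in out.patterns]
        assert keys == sorted(keys)

    def test_explosion_guard(self):
        # 12 identical transactions over 12 items: 2^12 - 1 frequent itemsets
        db = TransactionDB.from_itemsets([set(range(12))] * 12)
        with pytest.raises(MiningExplosionError, match="minsupp=1"):
            fp_growth(build_fp_tree(db, 1), 1, pattern_cap=100)

    def test_union_of_all_equals_union_of_maximal(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            db = random_db(rng)
            allp = fp_growth(build_fp_tree(db, 2), 2, mode="all")
            maxp = fp_growth(build_fp_tree(db, 2), 2, mode="maximal")
            assert allp.support_mask == maxp.support_mask


class TestMinePatterns:
    def test_minsupp_zero_clamped_with_warning(self, worked_db, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="glaret.local_stream"):
            out = mine_patterns(worked_db, 0, mode="all")
        assert "clamping" in caplog.text
        assert as_sets(out) == as_sets(mine_patterns(worked_db, 1, mode="all"))


class TestLocalFeature:
    def _part_spec(self, seed):
        rng = np.random.default_rng(seed)
        positions = frozenset(int(i) for i in rng.choice(49, size=5, replace=False))
        return SceneSpec(
            h=7, w=7, d=32,
            parts=(PartPlant(positions=positions, channels=tuple(range(10)), level=5.0),),
            noise=NoiseSpec(channels=tuple(range(10, 20)), items_per_channel=2,
                            level=1.0, max_item_support=1),
            seed=seed,
        )

    def test_planted_set_recovered_and_pooled(self):
        spec = self._part_spec(seed=3)
        tensor = generate_tensor(spec)
        planted = spec.parts[0].positions
        patterns = mine_patterns(build_transactions(tensor), minsupp=5, mode="maximal")
        assert patterns.support_mask == planted
        feat = local_feature(tensor, minsupp=5)
        region = Region(frozenset(divmod(i, 7) for i in planted))
        assert np.array_equal(feat.vector, pool_region(tensor, region).vector)

    def test_all_zero_tensor_fallback_zero_vector(self):
        feat = local_feature(ActivationTensor(np.zeros((3, 3, 4))), minsupp=1)
        assert np.array_equal(feat.vector, np.zeros(8))

    def test_unreachable_minsupp_falls_back_to_full_grid(self):
        rng = np.random.default_rng(0)
        t = ActivationTensor(rng.random((3, 3, 4)))
        feat = local_feature(t, minsupp=t.d + 1)
        assert np.array_equal(feat.vector, pool_region(t, full_grid_region(t)).vector)


class TestInterchange:
    def test_fimi_round_trip(self, worked_db, tmp_path):
        path = tmp_path / "txns.dat"
        write_transactions(worked_db, path)
        loaded = read_transactions(path)
        assert [t.items for t in loaded.transactions] == [
            t.items for t in worked_db.transactions
        ]

    def test_pattern_tsv(self, worked_db, tmp_path):
        path = tmp_path / "patterns.tsv"
        write_patterns(mine_patterns(worked_db, 2, mode="all"), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "items\tsupport"
        assert "0 1\t2" in lines
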