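"""Split protocols: random trained-location split and contiguous
location-blocked k-fold."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import wildtrap as wt
from conftest import make_catalog


def catalog_n(n, n_locs=4):
    return make_catalog(["A"] * n, [f"L{i % n_locs}" for i in range(n)])


class TestTrainedLocationSplit:
    def test_sizes_and_disjointness(self):
        cat = catalog_n(10)
        s = wt.trained_location_split(cat, test_fraction=0.1, seed=0)
        assert len(s.train_ids) == 9 and len(s.test_ids) == 1
        assert not (s.train_ids & s.test_ids)

    def test_seed_determinism_and_variation(self):
        cat = catalog_n(100)
        a = wt.trained_location_split(cat, 0.1, seed=4)
        b = wt.trained_location_split(cat, 0.1, seed=4)
        c = wt.trained_location_split(cat, 0.1, seed=5)
        assert a.test_ids == b.test_ids
        assert a.test_ids != c.test_ids

    def test_partition_holds_over_seed_sweep(self):
        cat = catalog_n(37)
        all_ids = {r.image_id for r in cat}
        for seed in range(100):
            s = wt.trained_location_split(cat, 0.2, seed=seed)
            assert s.train_ids | s.test_ids == all_ids
            assert not (s.train_ids & s.test_ids)

    def test_membership_frequency_uniform(self):
        # Monte-Carlo: with fraction 0.5 on N=20, each record lands in
        # test half the time (3 sigma binomial band over 2000 seeds)
        cat = catalog_n(20)
        n_seeds = 2000
        hits = {r.image_id: 0 for r in cat}
        for seed in range(n_seeds):
            for i in wt.trained_location_split(cat, 0.5, seed=seed).test_ids:
                hits[i] += 1
        sigma = np.sqrt(0.25 * n_seeds)
        for count in hits.values():
            assert abs(count - 0.5 * n_seeds) < 3 * sigma

    def test_augmented_records_forced_into_train(self):
        import dataclasses
        cat = catalog_n(10)
        aug = tuple(dataclasses.replace(r, image_id=r.image_id + "_aug0",
                                        is_augmented=True)
                    for r in cat.records[:3])
        cat2 = wt.Catalog(cat.records + aug)
        for seed in range(20):
            s = wt.trained_location_split(cat2, 0.3, seed=seed)
            assert all(a.image_id in s.train_ids for a in aug)

    def test_too_small_catalog_rejected(self):
        with pytest.raises(ValueError):
            wt.trained_location_split(catalog_n(1), 0.5, seed=0)


class TestFoldPlan:
    def test_five_locations_five_singleton_blocks(self):
        plan = wt.location_kfold_plan([f"L{i}" for i in range(5)], k=5)
        tests = [plan.folds[i][1] for i in range(5)]
        assert all(len(t) == 1 for t in tests)
        assert sorted(sum(tests, ())) == sorted(f"L{i}" for i in range(5))

    def test_36_locations_boundary_rule(self):
        locs = [f"L{i:02d}" for i in range(36)]
        plan = wt.location_kfold_plan(locs, k=5)
        sizes = tuple(len(plan.folds[i][1]) for i in range(5))
        assert sizes == (7, 7, 8, 7, 7)
        # contiguity: each test block is a contiguous run of the input
        start = 0
        for i in range(5):
            block = plan.folds[i][1]
            assert list(block) == locs[start:start + len(block)]
            start += len(block)

    def test_middle_block_pattern(self):
        locs = [f"L{i}" for i in range(1, 11)]
        plan = wt.location_kfold_plan(locs, k=5)
        train, test = plan.folds[1]
        assert test == ("L3", "L4")
        assert train == ("L1", "L2", "L5", "L6", "L7", "L8", "L9", "L10")

    @given(L=st.integers(2, 60), k=st.integers(2, 10))
    def test_block_sizes_differ_by_at_most_one(self, L, k):
        if L < k:
            with pytest.raises(ValueError):
                wt.location_kfold_plan([f"L{i}" for i in range(L)], k)
            return
        plan = wt.location_kfold_plan([f"L{i}" for i in range(L)], k)
        sizes = [len(plan.folds[i][1]) for i in range(k)]
        assert sum(sizes) == L
        assert max(sizes) - min(sizes) <= 1
        for train, test in plan.folds:
            assert sorted(train + test) == sorted(f"L{i}" for i in range(L))

    def test_plan_invariant_to_record_shuffles(self, small_world):
        # permuting images while keeping location first-appearance order
        # leaves the plan unchanged
        cat = small_world.catalog
        plan = wt.location_kfold_plan(cat.locations, k=3)
        recs = list(cat.records)
        rng = np.random.default_rng(0)
        # shuffle within the suffix after each location's first appearance
        first_ids = {loc: next(r.image_id for r in recs if r.location_id == loc)
                     for loc in cat.locations}
        head = [r for r in recs if r.image_id in set(first_ids.values())]
        head.sort(key=lambda r: cat.locations.index(r.location_id))
        tail = [r for r in recs if r.image_id not in set(first_ids.values())]
        rng.shuffle(tail)
        shuffled = wt.Catalog(tuple(head + tail))
        assert shuffled.locations == cat.locations
        assert wt.location_kfold_plan(shuffled.locations, k=3) == plan


@pytest.fixture(scope="module")
def world_and_plan(small_world):
    plan = wt.location_kfold_plan(small_world.catalog.locations, k=5)
    return small_world, plan


class TestMaterializeFold:

    def test_no_location_leakage_every_fold(self, world_and_plan):
        world, plan = world_and_plan
        for i in range(plan.k):
            s = wt.materialize_fold(world.catalog, plan, i)
            assert wt.verify_no_location_leakage(s, world.catalog)

    def test_folds_partition_all_images(self, world_and_plan):
        world, plan = world_and_plan
        seen = []
        for i in range(plan.k):
            seen.extend(wt.materialize_fold(world.catalog, plan, i).test_ids)
        assert sorted(seen) == sorted(r.image_id for r in world.catalog)

    def test_species_absent_from_blocked_training(self):
        # a species confined to a single test-fold location cannot
        # appear in that fold's training labels
        import numpy as np
        occ = np.ones((3, 5), dtype=int)
        occ[2] = 0
        occ[2, 0] = 1  # third species lives only at L01
        cfg = wt.SyntheticWorldConfig(
            n_locations=5, species=wt.synthetic.default_species(3),
            occupancy=occ, abundance=(10, 10, 6), no_animal_count=10, seed=2)
        world = wt.generate_world(cfg)
        cat = world.catalog
        loc_order = list(cat.locations)
        plan = wt.location_kfold_plan(loc_order, k=5)
        fold_of_L01 = next(i for i in range(5) if "L01" in plan.folds[i][1])
        s = wt.materialize_fold(cat, plan, fold_of_L01)
        confined = cfg.species[2].name
        train_labels = {cat.by_id(x).class_label for x in s.train_ids}
        test_labels = {cat.by_id(x).class_label for x in s.test_ids}
        assert confined in test_labels
        assert confined not in train_labels

    def test_leakage_detector_flags_random_split(self, small_world):
        s = wt.trained_location_split(small_world.catalog, 0.3, seed=0)
        assert not wt.verify_no_location_leakage(s, small_world.catalog)

    def test_leakage_detector_flags_hand_built_leak(self):
        cat = make_catalog(["A"] * 6, ["L1", "L1", "L2", "L2", "L3", "L3"])
        from wildtrap.splits import SplitAssignment, UNTRAINED
        leaky = SplitAssignment(UNTRAINED,
                                frozenset({"r0", "r1", "r2"}),
                                frozenset({"r3", "r4", "r5"}))
        assert not wt.verify_no_location_leakage(leaky, cat)
        clean = SplitAssignment(UNTRAINED,
                                frozenset({"r0", "r1", "r2", "r3"}),
                                frozenset({"r4", "r5"}))
        assert wt.verify_no_location_leakage(clean, cat)
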