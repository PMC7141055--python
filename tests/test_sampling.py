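"""Ratio table, rejection-resampling stream (checked against an
independent analytic enumeration oracle), and supplementation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import wildtrap as wt
from wildtrap.augment import AugmentationConfig
from conftest import flat_images, make_catalog


def expected_class_freqs(counts: dict, max_redraws: int) -> dict:
    """Independent enumeration oracle for the rejection loop.

    One loop iteration draws a record (class c w.p. p_c = n_c/N) and a
    uniform u; it accepts class c when u > r_c (probability p_c(1-r_c))
    and otherwise repeats, so iterations continue with probability
    q = sum_c p_c r_c.  After M fruitless iterations the last draw is
    emitted, contributing q^{M-1} p_c r_c to class c.  Summing the
    geometric series over at most M iterations:

        P(c) = p_c (1-r_c) (1 - q^M) / (1 - q)  +  q^{M-1} p_c r_c
    """
    N = sum(counts.values())
    n_max = max(counts.values())
    p = {c: n / N for c, n in counts.items()}
    r = {c: n / n_max for c, n in counts.items()}
    q = sum(p[c] * r[c] for c in counts)
    M = max_redraws
    out = {}
    for c in counts:
        if q == 1.0:  # all ratios 1: loop never accepts, cap emits p_c
            out[c] = p[c]
        else:
            out[c] = p[c] * (1 - r[c]) * (1 - q**M) / (1 - q) + q ** (M - 1) * p[c] * r[c]
    assert abs(sum(out.values()) - 1.0) < 1e-12
    return out


def empirical_freqs(counts, max_redraws, n_emit, seed=0):
    labels = [c for c, n in counts.items() for _ in range(n)]
    cat = make_catalog(labels)
    ratios = wt.compute_class_ratios(counts)
    stream = wt.rebalanced_stream(cat, ratios, wt.SamplerConfig(max_redraws, seed))
    tally = {c: 0 for c in counts}
    for rec in itertools.islice(stream, n_emit):
        tally[rec.class_label] += 1
    return {c: t / n_emit for c, t in tally.items()}


class TestClassRatios:
    def test_balanced_counts(self):
        assert wt.compute_class_ratios({"A": 50, "B": 50}).ratios == {"A": 1.0, "B": 1.0}

    def test_direct_division(self):
        t = wt.compute_class_ratios({"A": 90, "B": 10})
        assert t.ratios["A"] == 1.0
        assert t.ratios["B"] == pytest.approx(1 / 9)

    def test_fixture_deer_ratio(self, table1):
        counts = {r.class_label: r.n_train for r in table1}
        t = wt.compute_class_ratios(counts)
        assert t.ratios["White-tailed Deer"] == pytest.approx(7484 / 8566)
        assert t.ratios["No Animal"] == 1.0

    @given(scale=st.integers(1, 50),
           ns=st.lists(st.integers(1, 40), min_size=2, max_size=6))
    def test_scale_invariance(self, scale, ns):
        counts = {f"c{i}": n for i, n in enumerate(ns)}
        scaled = {c: n * scale for c, n in counts.items()}
        a = wt.compute_class_ratios(counts).ratios
        b = wt.compute_class_ratios(scaled).ratios
        assert all(a[c] == pytest.approx(b[c]) for c in counts)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            wt.compute_class_ratios({})


class TestRebalancedStream:
    def test_single_class_uniform_over_records(self):
        # only class has r=1: every emission goes through the cap path
        cat = make_catalog(["A"] * 5)
        stream = wt.rebalanced_stream(cat, wt.compute_class_ratios({"A": 5}),
                                      wt.SamplerConfig(seed=1))
        tally = {}
        n = 20000
        for rec in itertools.islice(stream, n):
            tally[rec.image_id] = tally.get(rec.image_id, 0) + 1
        sigma = np.sqrt(0.2 * 0.8 * n)
        for c in tally.values():
            assert abs(c - n / 5) < 3 * sigma

    def test_seed_determinism(self):
        a = empirical_freqs({"A": 9, "B": 3}, 10, 2000, seed=7)
        b = empirical_freqs({"A": 9, "B": 3}, 10, 2000, seed=7)
        assert a == b

    @pytest.mark.parametrize("counts", [
        {"A": 90, "B": 10},
        {"A": 40, "B": 30, "C": 2},
    ])
    def test_matches_enumeration_oracle(self, counts):
        n = 100_000
        emp = empirical_freqs(counts, 10, n, seed=3)
        exp = expected_class_freqs(counts, 10)
        for c, p in exp.items():
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(emp[c] - p) < 3 * sigma, (c, emp[c], p)

    def test_minority_always_upweighted(self):
        n = 100_000
        for counts in ({"A": 90, "B": 10}, {"A": 60, "B": 25}):
            emp = empirical_freqs(counts, 10, n, seed=5)
            raw = counts["B"] / sum(counts.values())
            p = expected_class_freqs(counts, 10)["B"]
            sigma = np.sqrt(p * (1 - p) / n)
            assert emp["B"] - 3 * sigma > raw

    def test_cap_one_with_tiny_ratios_approaches_raw_proportions(self):
        # with max_redraws=1 and all r_c -> 0 the accept branch fires on
        # the first draw almost surely, leaving plain uniform sampling
        counts = {"A": 3000, "B": 1}
        exp = expected_class_freqs(counts, 1)
        raw = {c: n / sum(counts.values()) for c, n in counts.items()}
        assert exp["A"] == pytest.approx(raw["A"], abs=1e-3)

    def test_uncovered_class_rejected(self):
        cat = make_catalog(["A", "B"])
        with pytest.raises(ValueError, match="B"):
            next(wt.rebalanced_stream(cat, wt.compute_class_ratios({"A": 1}),
                                      wt.SamplerConfig()))


class TestSupplementation:
    def loader(self, rec):
        rng = np.random.default_rng(abs(hash(rec.image_id)) % 2**31)
        return rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)

    def test_deficit_filled_exactly(self):
        cat = make_catalog(["Woodrat"] * 8 + ["Marten"] * 12)
        out, imgs = wt.supplement_to_minimum(cat, 10, AugmentationConfig(),
                                             seed=0, loader=self.loader)
        counts = wt.class_counts(out)
        assert counts == {"Woodrat": 10, "Marten": 12}
        assert wt.class_counts(out, include_augmented=False)["Woodrat"] == 8
        assert len(imgs) == 2
        assert all(out.by_id(i).is_augmented for i in imgs)

    def test_large_deficit_cycles_sources(self):
        cat = make_catalog(["W"] * 8)
        out, imgs = wt.supplement_to_minimum(cat, 100, AugmentationConfig(),
                                             seed=0, loader=self.loader)
        assert len(imgs) == 92
        assert wt.class_counts(out)["W"] == 100

    def test_class_at_threshold_untouched(self):
        cat = make_catalog(["M"] * 100)
        out, imgs = wt.supplement_to_minimum(cat, 100, AugmentationConfig(),
                                             seed=0, loader=self.loader)
        assert imgs == {} and len(out) == 100

    def test_determinism(self):
        cat = make_catalog(["A"] * 3 + ["B"] * 7)
        a_cat, a_imgs = wt.supplement_to_minimum(cat, 6, AugmentationConfig(),
                                                 seed=4, loader=self.loader)
        b_cat, b_imgs = wt.supplement_to_minimum(cat, 6, AugmentationConfig(),
                                                 seed=4, loader=self.loader)
        assert a_cat == b_cat
        assert set(a_imgs) == set(b_imgs)
        assert all(np.array_equal(a_imgs[k], b_imgs[k]) for k in a_imgs)

    def test_augmented_only_class_rejected(self):
        import dataclasses
        cat = make_catalog(["A", "B"])
        only_aug = wt.Catalog((
            cat.records[0],
            dataclasses.replace(cat.records[1], is_augmented=True),
        ))
        with pytest.raises(ValueError, match="B"):
            wt.supplement_to_minimum(only_aug, 5, AugmentationConfig(),
                                     seed=0, loader=self.loader)
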