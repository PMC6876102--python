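"""Distance test: null construction, p-values, BH, entropy filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexsig.distance import (
    DistanceTestConfig,
    FragmentClassNull,
    NullBank,
    UndefinedEntropyError,
    bh_adjust,
    build_null,
    classify_first,
    entropy_split,
    normalized_entropy,
    raw_pvalue,
    run_distance_test,
    second_pass,
    step_statistics,
)
from plexsig.model import distance_profile

from conftest import make_complex


def bh_oracle(pvals, fdr):
    """Literal step-up: reject 1..k for the largest k with p_(k) <= fdr*k/m."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= fdr * i / m:
            k = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def _cfg(**kw):
    kw.setdefault("sample_size", 1000)
    return DistanceTestConfig(**kw)


class TestBuildNull:
    def test_mean_total_distance_matches_expectation(self):
        # bucket {500, 4500}: a class-3 expected complex sums 2 draws,
        # so E[d_tot] = 2 * mean(B) = 5000
        cxs = [make_complex("a", [(100, 500), (1000, 1500), (6000, 6500)])]
        bank = build_null(cxs, _cfg(sample_size=50_000, seed=7))
        mean = bank[3].d_tot_samples.mean()
        assert abs(mean - 5000) < 3 * np.sqrt(2) * 2000 / np.sqrt(50_000)

    def test_same_seed_gives_identical_samples(self):
        cxs = [make_complex("a", [(0, 10), (500, 510), (9000, 9010)])]
        b1 = build_null(cxs, _cfg(seed=3))
        b2 = build_null(cxs, _cfg(seed=3))
        assert np.array_equal(b1[3].d_tot_samples, b2[3].d_tot_samples)

    def test_singleton_bucket_degenerates(self):
        # bucket {d}: every class-j expected complex totals (j-1)*d and
        # has uniform gaps, hence entropy exactly 1
        cxs = [make_complex("a", [(0, 100), (1100, 1200)])]
        bank = build_null(cxs, _cfg())
        null4 = bank[4]
        assert np.all(null4.d_tot_samples == 3 * 1000)
        assert null4.mean_entropy == pytest.approx(1.0)

    def test_empty_bucket_is_an_error(self):
        with pytest.raises(ValueError, match="bucket"):
            NullBank(np.empty(0, dtype=np.int64), _cfg(), "chrX")


class TestRawPvalue:
    def test_count_oracle(self):
        null = FragmentClassNull(3, np.array([1, 2, 3, 4, 10]), 1.0, 5)
        assert raw_pvalue(5, null) == pytest.approx(0.8)

    def test_extremes(self):
        null = FragmentClassNull(3, np.array([5, 6, 7, 8]), 1.0, 4)
        assert raw_pvalue(1, null) == 0.0
        assert raw_pvalue(100, null) == 1.0

    def test_monotone_in_observation(self, rng):
        null = FragmentClassNull(3, np.sort(rng.integers(1, 10**6, 1000)), 1.0, 1000)
        obs = np.sort(rng.integers(1, 10**6, 50))
        p = raw_pvalue(obs, null)
        assert np.all(np.diff(p) >= 0)


class TestBHAdjust:
    def test_hand_oracle(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.5], 0.1)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_single_and_constant_vectors_unchanged(self):
        adj, _ = bh_adjust([0.3], 0.1)
        assert adj[0] == pytest.approx(0.3)
        adj, _ = bh_adjust([0.2, 0.2, 0.2], 0.1)
        assert np.allclose(adj, 0.2)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
        st.floats(0.01, 0.5),
    )
    def test_mask_matches_step_up_oracle(self, pvals, fdr):
        _, sig = bh_adjust(pvals, fdr)
        assert np.array_equal(sig, bh_oracle(pvals, fdr))


class TestNormalizedEntropy:
    def test_hand_oracle_skewed_pair(self):
        # (0.1 log2 10 + 0.9 log2(10/9)) / log2 2
        assert normalized_entropy([0.1, 0.9]) == pytest.approx(0.469, abs=1e-3)

    @pytest.mark.parametrize(
        "p,expected",
        [([0.5, 0.5], 1.0), ([1 / 3] * 3, 1.0), ([1.0, 0.0], 0.0)],
    )
    def test_bounds_attained(self, p, expected):
        assert normalized_entropy(p) == pytest.approx(expected)

    def test_undefined_for_two_fragment_class(self):
        with pytest.raises(UndefinedEntropyError):
            normalized_entropy([1.0])

    def test_in_unit_interval_on_random_vectors(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            p = rng.dirichlet(np.ones(k) * rng.uniform(0.1, 5))
            h = normalized_entropy(p)
            assert 0.0 <= h <= 1.0 + 1e-12

    def test_monotone_decrease_toward_degenerate(self):
        hs = [
            normalized_entropy([q, 1 - q]) for q in (0.5, 0.6, 0.75, 0.9, 0.99)
        ]
        assert all(a > b for a, b in zip(hs, hs[1:]))


class TestEntropySplit:
    def test_low_entropy_complex_cut_at_largest_gap(self, worked_example):
        # H = 0.469 < 0.7; the second gap (500) is < 4500/2, single cut
        parts = entropy_split(worked_example, threshold=0.7, tau=2.0)
        assert [p.n for p in parts] == [2, 1]
        assert parts[0].fragments[-1].end == 1500
        assert all(p.parent_id == "OC8" for p in parts)

    def test_high_entropy_complex_unchanged(self):
        c = make_complex("c", [(0, 100), (600, 700), (1200, 1300)])
        assert entropy_split(c, threshold=0.99, tau=2.0) == (c,)

    def test_second_cut_yields_three_subcomplexes(self):
        # gaps [4000, 100, 4500]; 4000 >= 4500/2 so both large gaps cut
        c = make_complex(
            "t", [(0, 100), (4100, 4200), (4300, 4400), (8900, 9000)]
        )
        x = distance_profile(c).x_f2f
        assert x.tolist() == [4000, 100, 4500]
        h = normalized_entropy(distance_profile(c).p_f2f)
        parts = entropy_split(c, threshold=h + 0.01, tau=2.0)
        assert [p.n for p in parts] == [1, 2, 1]

    def test_fragment_multiset_preserved(self, worked_example):
        parts = entropy_split(worked_example, threshold=0.7, tau=2.0)
        frags = [f for p in parts for f in p.fragments]
        assert frags == list(worked_example.fragments)


class TestClassification:
    def _toy_set(self):
        # 30 compact + 10 stretched class-3 complexes and 10 compact +
        # 10 stretched class-2 complexes
        cxs = []
        for i in range(30):
            o = i * 100_000
            cxs.append(make_complex(f"c{i}", [(o, o + 100), (o + 600, o + 700),
                                              (o + 1200, o + 1300)]))
        for i in range(10):
            o = 5_000_000 + i * 1_000_000
            cxs.append(make_complex(f"s{i}", [(o, o + 100),
                                              (o + 400_000, o + 400_100),
                                              (o + 900_000, o + 900_100)]))
        for i in range(10):
            o = 16_000_000 + i * 10_000
            cxs.append(make_complex(f"p{i}", [(o, o + 100), (o + 700, o + 800)]))
        for i in range(10):
            o = 17_000_000 + i * 800_000
            cxs.append(make_complex(f"q{i}", [(o, o + 100),
                                              (o + 500_000, o + 500_100)]))
        return cxs

    def test_first_pass_categories(self):
        cxs = self._toy_set()
        cfg = _cfg(seed=11)
        bank = build_null(cxs, cfg)
        classify_first(cxs, bank, cfg)
        cats = {c.id: c.category for c in cxs}
        # compact class-3 complexes pass; stretched ones defer (n > 2)
        assert all(cats[f"c{i}"] == "pass1" for i in range(30))
        assert all(cats[f"s{i}"] == "defer" for i in range(10))
        # insignificant two-fragment complexes fail outright
        assert all(cats[f"q{i}"] == "fail1" for i in range(10))

    def test_max_frags_fail_caps_first_pass(self):
        cxs = self._toy_set()
        cfg = _cfg(seed=11, max_frags_fail=2)
        bank = build_null(cxs, cfg)
        classify_first(cxs, bank, cfg)
        # stretched class-3 complexes now exceed the cap and fail
        assert all(c.category == "fail1" for c in cxs if c.id.startswith("s"))

    def test_second_pass_singletons_not_tested(self):
        cxs = self._toy_set()
        cfg = _cfg(seed=11)
        bank = build_null(cxs, cfg)
        single = make_complex("solo", [(0, 100)])
        compact = make_complex("sub", [(0, 100), (600, 700)], parent_id="x")
        out = second_pass([single, compact], bank, cfg)
        assert single.category == "singleton"
        assert single.raw_p is None
        assert compact.category in ("pass2", "fail2")


class TestRunDistanceTest:
    def _dataset(self, seed=5):
        from plexsig.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_complexes=800, noise_fraction=0.5, multiplet_fraction=0.1,
            seed=seed,
        )
        return simulate_dataset(cfg)

    def test_every_complex_ends_in_exactly_one_category(self):
        ds = self._dataset()
        master = run_distance_test(
            ds.complexes_by_chrom(), _cfg(seed=5)
        )
        assert len(master) >= len(ds.complexes)
        roots = master[master.parent_id.isna()]
        assert set(roots.complex_id) == {c.id for c in ds.complexes}
        assert set(roots.category) <= {"pass1", "fail1", "pass2", "fail2", "split"}
        children = master[master.parent_id.notna()]
        assert set(children.category) <= {"pass2", "fail2", "singleton"}
        # split parents decompose into their children exactly
        for pid, grp in children.groupby("parent_id"):
            parent = roots[roots.complex_id == pid].iloc[0]
            child_frags = ";".join(grp.sort_values("start").fragments)
            assert child_frags == parent.fragments

    def test_fixed_seed_reproduces_master_table(self, tmp_path):
        from plexsig import io

        ds = self._dataset()
        for run in ("a", "b"):
            master = run_distance_test(ds.complexes_by_chrom(), _cfg(seed=5))
            io.write_master(master, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_homogeneous_compact_dataset_is_all_significant(self):
        # every gap equals 1 kb, so each observed total equals the null
        # total exactly and no expected complex is strictly shorter
        cxs = []
        for i in range(50):
            o = i * 50_000
            coords = [(o + k * 1100, o + k * 1100 + 100) for k in range(6)]
            cxs.append(make_complex(f"c{i}", coords))
        master = run_distance_test(cxs, _cfg(seed=9))
        assert (master.category == "pass1").all()

    def test_sparse_chromosome_skipped_with_warning(self):
        cxs = [make_complex("only", [(0, 100), (600, 700)])]
        cfg = _cfg(seed=1, min_complexes=5)
        with pytest.warns(UserWarning, match="skipping"):
            master = run_distance_test(cxs, cfg)
        assert len(master) == 0

    def test_significant_distances_stochastically_shorter(self):
        from plexsig.simulate import SimulationConfig, simulate_dataset
        from plexsig.io import master_to_complexes
        from scipy.stats import ks_2samp

        ds = self._dataset(seed=6)
        master = run_distance_test(ds.complexes_by_chrom(), _cfg(seed=6))
        sig = master_to_complexes(master, ["PASS"])
        all_gaps = np.concatenate(
            [distance_profile(c).x_f2f for c in ds.complexes if c.n >= 2]
        )
        sig_gaps = np.concatenate(
            [distance_profile(c).x_f2f for c in sig["chrS"]]
        )
        ks = ks_2samp(sig_gaps, all_gaps)
        assert ks.statistic > 0
        # direction: significant complexes have the shorter distances
        assert np.median(sig_gaps) < np.median(all_gaps)


class TestStepStatistics:
    def test_counts_are_consistent(self):
        from plexsig.simulate import SimulationConfig, simulate_dataset

        ds = simulate_dataset(
            SimulationConfig(n_complexes=500, noise_fraction=0.3,
                             multiplet_fraction=0.2, seed=8)
        )
        master = run_distance_test(ds.complexes_by_chrom(), _cfg(seed=8))
        stats = step_statistics(master)
        assert stats["input"] == 500
        assert stats["significant"] == stats["pass1"] + stats["pass2"]
        assert (
            stats["pass1"] + stats["fail1"] + stats["defer"] == stats["input"]
        )
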