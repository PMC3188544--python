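"""Binning, one-tailed conversion, matched null sets, fine-mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from transheight.errors import DegenerateInputError, MatchingError
from transheight.ld import LDCache
from transheight.replication import (
    Bin,
    build_bins,
    count_significant_bins,
    empirical_p,
    fine_map_best,
    generate_matched_sets,
    one_tailed,
    run_replication,
)


class StubLD:
    """Pairwise r^2 oracle backed by a dict (tests only)."""

    def __init__(self, r2_by_pair, ids):
        self._r2 = {frozenset(k): v for k, v in r2_by_pair.items()}
        self._ids = list(ids)

    def r2_ids(self, a, b):
        return self._r2.get(frozenset((a, b)), 0.0)


def oracle_greedy(order, r2, threshold):
    """Independent re-implementation of greedy binning for enumeration."""
    remaining = list(order)
    bins = []
    while remaining:
        idx = remaining.pop(0)
        members = [s for s in remaining if r2.r2_ids(idx, s) >= threshold]
        for s in members:
            remaining.remove(s)
        bins.append((idx, [idx] + members))
    return bins


class TestOneTailed:
    def test_direction_match_halves(self):
        assert one_tailed(0.05, "+", "+") == pytest.approx(0.025)

    def test_direction_mismatch_complements(self):
        assert one_tailed(0.05, "-", "+") == pytest.approx(0.975)

    def test_p_one_gives_half(self):
        assert one_tailed(1.0, "+", "+") == 0.5
        assert one_tailed(1.0, "-", "+") == 0.5

    def test_zero_effect_is_half(self):
        assert one_tailed(0.3, 0, "+") == 0.5

    def test_numeric_signs(self):
        assert one_tailed(0.1, -1.0, -1) == pytest.approx(0.05)

    def test_invalid_p(self):
        with pytest.raises(DegenerateInputError):
            one_tailed(0.0, "+", "+")
        with pytest.raises(DegenerateInputError):
            one_tailed(1.2, "+", "+")


class TestBuildBins:
    def test_all_independent_all_singletons(self):
        ld = StubLD({}, ["a", "b", "c"])
        bins = build_bins(["a", "b", "c"], ld, seed=0)
        assert len(bins) == 3
        assert all(b.size == 1 for b in bins)

    def test_all_linked_one_bin(self):
        pairs = {("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9}
        ld = StubLD(pairs, "abc")
        bins = build_bins(["a", "b", "c"], ld, seed=0)
        assert len(bins) == 1
        assert sorted(bins[0].members) == ["a", "b", "c"]

    def test_chain_enumeration_oracle(self):
        # A-B r2=0.5, B-C r2=0.5, A-C r2=0.1: B first -> 1 bin, else 2
        ld = StubLD({("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.1},
                    "abc")
        expected = {}
        for order in itertools.permutations(["a", "b", "c"]):
            expected[order] = len(oracle_greedy(list(order), ld, 0.3))
        assert set(expected.values()) == {1, 2}
        assert expected[("b", "a", "c")] == 1
        # build_bins realizes exactly this distribution over seeds
        observed = {
            len(build_bins(["a", "b", "c"], ld, seed=s)) for s in range(40)
        }
        assert observed == {1, 2}

    def test_partition_property_on_panel(self, panels):
        src, _ = panels
        ld = LDCache(src)
        poly = np.flatnonzero(src.is_polymorphic())
        ids = [src.variants["id"].iat[int(i)] for i in poly[40:60]]
        for seed in range(8):
            bins = build_bins(ids, ld, seed=seed)
            members = [s for b in bins for s in b.members]
            assert sorted(members) == sorted(ids)  # disjoint cover

    def test_deterministic_under_seed(self, panels):
        src, _ = panels
        ld = LDCache(src)
        ids = [src.variants["id"].iat[int(i)]
               for i in np.flatnonzero(src.is_polymorphic())[:15]]
        a = build_bins(ids, ld, seed=5)
        b = build_bins(ids, ld, seed=5)
        assert [x.members for x in a] == [x.members for x in b]

    def test_empty_input(self):
        assert build_bins([], StubLD({}, []), seed=0) == []


class TestCountSignificantBins:
    def test_hand_enumerated_fixture(self):
        # 10 loci, 23 bins with known one-tailed P assignments
        rng = np.random.default_rng(0)
        bins_by_locus = {}
        p_lookup = {}
        expected_total = 0
        k = 0
        for locus in range(10):
            n_bins = [1, 2, 3, 2, 1, 4, 2, 3, 2, 3][locus]
            bins = []
            for b in range(n_bins):
                idx = f"snp{k}"
                p = [0.01, 0.5, 0.04, 0.9, 0.05, 0.2][k % 6]
                p_lookup[idx] = p
                if p <= 0.05:
                    expected_total += 1
                bins.append(Bin(index=idx, members=[idx]))
                k += 1
            bins_by_locus[f"locus{locus}"] = bins
        assert k == 23
        per_locus, total = count_significant_bins(bins_by_locus, p_lookup)
        assert total == expected_total
        assert sum(per_locus.values()) == total

    def test_all_p_one_gives_zero(self):
        bins = {"L": [Bin("a", ["a"]), Bin("b", ["b"])]}
        _, total = count_significant_bins(bins, {"a": 1.0, "b": 1.0})
        assert total == 0

    def test_missing_p_excluded_with_warning(self, caplog):
        bins = {"L": [Bin("a", ["a"]), Bin("b", ["b"])]}
        per_locus, total = count_significant_bins(bins, {"a": 0.01})
        assert total == 1

    def test_invariant_to_locus_and_member_order(self):
        bins = {
            "L1": [Bin("a", ["a", "x"]), Bin("b", ["b"])],
            "L2": [Bin("c", ["c"])],
        }
        p = {"a": 0.01, "b": 0.2, "c": 0.03}
        _, t1 = count_significant_bins(bins, p)
        flipped = {"L2": bins["L2"], "L1": bins["L1"][::-1]}
        _, t2 = count_significant_bins(flipped, p)
        assert t1 == t2 == 2


class TestEmpiricalP:
    def test_one_in_5819(self):
        nulls = np.zeros(5_819)
        nulls[0] = 200  # one null set at least as extreme
        res = empirical_p(171, nulls)
        assert res.p == pytest.approx(1.7e-4, rel=0.02)

    def test_observed_below_all_nulls(self):
        assert empirical_p(1, [5, 8, 3]).p == 1.0

    def test_below_resolution_reporting(self):
        res = empirical_p(50, np.arange(100))  # nulls 0..99: all < ... no
        res = empirical_p(150, np.arange(100))
        assert res.below_resolution
        assert res.p == 0.0
        assert str(res) == "< 0.01"

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            empirical_p(1, [])


class TestMatchedSets:
    def test_pool_of_loci_gives_permutations(self):
        mafs = [0.1, 0.2, 0.3, 0.4]
        pool = pd.DataFrame({"snp": list("abcd"), "maf": mafs})
        ld = StubLD({}, "abcd")
        out = generate_matched_sets(mafs, pool, ld, n_sets=10, maf_tol=0.01,
                                    seed=0)
        for s in out.sets:
            assert sorted(s) == list("abcd")
            assert s == ["a", "b", "c", "d"]  # tight tolerance: identity

    def test_equal_mafs_give_shuffles(self):
        pool = pd.DataFrame({"snp": list("abcde"), "maf": [0.2] * 5})
        ld = StubLD({}, "abcde")
        out = generate_matched_sets([0.2] * 5, pool, ld, n_sets=20,
                                    maf_tol=0.01, seed=1)
        assert all(sorted(s) == list("abcde") for s in out.sets)
        assert len({tuple(s) for s in out.sets}) > 1

    def test_invariant_audit_on_panel(self, panels):
        src, _ = panels
        ld = LDCache(src)
        maf = src.maf()
        ids = src.variants["id"].to_numpy()
        common = maf >= 0.05
        pool = pd.DataFrame({"snp": ids[common], "maf": maf[common]})
        rng = np.random.default_rng(3)
        index_mafs = rng.choice(pool["maf"].to_numpy(), 12, replace=False)
        out = generate_matched_sets(index_mafs, pool, ld, n_sets=25,
                                    maf_tol=0.02, r2_indep=0.2, seed=4)
        maf_map = dict(zip(pool["snp"], pool["maf"]))
        for s in out.sets:
            assert len(s) == 12 and len(set(s)) == 12
            for li, (m, target) in enumerate(zip(s, index_mafs)):
                assert abs(maf_map[m] - target) <= out.maf_tol_used[li] + 1e-12
            # pairwise independence within the proxy window
            for a, b in itertools.combinations(s, 2):
                ia, ib = ld.index_of(a), ld.index_of(b)
                pa = src.variants["pos"].iat[ia]
                pb = src.variants["pos"].iat[ib]
                if abs(pa - pb) <= 1_000_000:
                    assert ld.d_r2(ia, ib)[1] < 0.2

    def test_maf_distribution_matches(self, panels):
        src, _ = panels
        ld = LDCache(src)
        maf = src.maf()
        ids = src.variants["id"].to_numpy()
        common = maf >= 0.05
        pool = pd.DataFrame({"snp": ids[common], "maf": maf[common]})
        rng = np.random.default_rng(5)
        index_mafs = rng.choice(pool["maf"].to_numpy(), 30, replace=False)
        out = generate_matched_sets(index_mafs, pool, ld, n_sets=30,
                                    maf_tol=0.02, seed=6)
        maf_map = dict(zip(pool["snp"], pool["maf"]))
        pooled = np.array([maf_map[m] for s in out.sets for m in s])
        # two-sample KS against the index MAFs
        from scipy.stats import ks_2samp

        assert ks_2samp(pooled, index_mafs).pvalue > 0.01

    def test_impossible_matching_raises(self):
        pool = pd.DataFrame({"snp": ["a"], "maf": [0.10]})
        ld = StubLD({}, "a")
        with pytest.raises(MatchingError):
            generate_matched_sets([0.45], pool, ld, n_sets=5, maf_tol=0.02,
                                  seed=0)


class TestFineMap:
    def test_single_snp_locus(self):
        res = fine_map_best(["a"], StubLD({}, "a"), {"a": 0.3})
        assert res.best_snp == "a"
        assert res.best_p == 0.3

    def test_proxy_with_smaller_p_replaces_index(self):
        # mirrors a proxy overtaking the reported index SNP
        ld = StubLD({("idx", "proxy"): 0.55}, ["idx", "proxy"])
        res = fine_map_best(["idx", "proxy"], ld,
                            {"idx": 0.0025, "proxy": 2.9e-7},
                            positions={"idx": 100, "proxy": 200})
        assert res.best_snp == "proxy"

    def test_bonferroni_flag(self):
        res = fine_map_best(["a"], StubLD({}, "a"), {"a": 1e-5},
                            bonferroni_m=161)
        assert res.passes_bonferroni  # 1e-5 < 0.05/161 = 3.1e-4
        res2 = fine_map_best(["a"], StubLD({}, "a"), {"a": 0.01},
                             bonferroni_m=161)
        assert not res2.passes_bonferroni

    @pytest.mark.parametrize("seed", range(5))
    def test_best_p_bounded_by_any_randomized_binning(self, seed):
        # exhaustive over all orders of a <=6-SNP locus: the P-sorted
        # index P can never exceed any randomized bin index P minimum
        rng = np.random.default_rng(seed)
        ids = list("abcdef")
        pairs = {}
        for a, b in itertools.combinations(ids, 2):
            pairs[(a, b)] = rng.choice([0.0, 0.2, 0.5, 0.9])
        ld = StubLD(pairs, ids)
        p_lookup = {s: rng.random() for s in ids}
        pos = {s: k for k, s in enumerate(ids)}
        res = fine_map_best(ids, ld, p_lookup, positions=pos)
        for order in itertools.permutations(ids):
            bins = oracle_greedy(list(order), ld, 0.3)
            assert res.best_p <= min(p_lookup[b[0]] for b in bins) + 1e-15

    def test_empty_locus(self):
        assert fine_map_best([], StubLD({}, []), {}) is None


class TestRunReplication:
    def test_zero_loci_empty_report(self, panels):
        src, tgt = panels
        meta = pd.DataFrame({"SNP": [], "BETA": [], "P": []})
        report = run_replication([], src, tgt, meta, n_sets=10, seed=0)
        assert report.observed_total == 0
        assert report.empirical_p is None
        assert report.per_locus == []

    def test_smoke_report_consistency(self, panels):
        src, tgt = panels
        ld = LDCache(src)
        maf = src.maf()
        ids = src.variants["id"].to_numpy()
        rng = np.random.default_rng(9)
        common = np.flatnonzero(maf >= 0.05)
        picks = rng.choice(common, 12, replace=False)
        alt = src.variants["alt"].to_numpy()
        pairs = [(ids[i], alt[i]) for i in picks]
        meta = pd.DataFrame(
            {"SNP": ids, "BETA": rng.normal(0, 0.05, ids.size),
             "P": rng.random(ids.size)}
        )
        report = run_replication(pairs, src, tgt, meta, n_sets=25, seed=3)
        assert report.n_loci == 12
        assert report.observed_total == sum(
            d.n_significant for d in report.per_locus
        )
        assert report.null_counts.size == 25
        assert 0.0 <= report.empirical_p.p <= 1.0
        s = report.summary()
        assert s["n_null_sets"] == 25

    def test_deterministic(self, panels):
        src, tgt = panels
        ids = src.variants["id"].to_numpy()
        maf = src.maf()
        rng = np.random.default_rng(10)
        picks = rng.choice(np.flatnonzero(maf >= 0.1), 8, replace=False)
        alt = src.variants["alt"].to_numpy()
        pairs = [(ids[i], alt[i]) for i in picks]
        meta = pd.DataFrame(
            {"SNP": ids, "BETA": rng.normal(0, 0.05, ids.size),
             "P": rng.random(ids.size)}
        )
        r1 = run_replication(pairs, src, tgt, meta, n_sets=15, seed=5)
        r2 = run_replication(pairs, src, tgt, meta, n_sets=15, seed=5)
        assert r1.observed_total == r2.observed_total
        assert np.array_equal(r1.null_counts, r2.null_counts)
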