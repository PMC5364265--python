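"""The prefix-scan statistic, permutation null, e-values, and BH adjustment."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idea.core import (
    PrefixEnrichmentProfile,
    NullDistribution,
    bh_adjust,
    empirical_e_value,
    fisher_prefix_p,
    min_p_statistic,
    permutation_null,
    prefix_profile,
    run_idea,
)
from idea.expression import RankedGeneList
from idea.gene_sets import GeneSetCollection
from idea.synthetic_data import permute_ranking


def exact_upper_tail(hits: int, n: int, K: int, U: int) -> Fraction:
    """Exhaustive hypergeometric enumeration: P(X >= hits) as a Fraction."""
    total = comb(U, n)
    acc = sum(comb(K, j) * comb(U - K, n - j)
              for j in range(hits, min(n, K) + 1))
    return Fraction(acc, total)


def naive_full_scan(ranked: RankedGeneList, category: set, universe: set):
    """Independent oracle: Fisher p at every n in 1..N, exact arithmetic."""
    U, K = len(universe), len(category & universe)
    hits = 0
    best, best_n = Fraction(1), 1
    for n, gene in enumerate(ranked.genes, start=1):
        if gene in category:
            hits += 1
        f = exact_upper_tail(hits, n, K, U) if hits else Fraction(1)
        if f < best:
            best, best_n = f, n
    return best, best_n


def make_list(genes, direction="up"):
    n = len(genes)
    return RankedGeneList(list(genes), np.linspace(2.0, 0.1, n), direction)


class TestFisherPrefixP:
    def test_zero_hits_is_exactly_one(self):
        assert fisher_prefix_p(0, 5, 3, 20) == 1.0

    @pytest.mark.parametrize(
        "hits,n,K,U",
        [(3, 3, 5, 20), (2, 5, 5, 20), (1, 1, 1, 10), (5, 10, 5, 30)],
    )
    def test_matches_exhaustive_enumeration(self, hits, n, K, U):
        expected = float(exact_upper_tail(hits, n, K, U))
        assert fisher_prefix_p(hits, n, K, U) == pytest.approx(expected, rel=1e-12)

    def test_known_closed_forms(self):
        # C(5,3)/C(20,3) = 10/1140
        assert fisher_prefix_p(3, 3, 5, 20) == pytest.approx(10 / 1140, rel=1e-12)
        assert fisher_prefix_p(2, 5, 5, 20) == pytest.approx(0.3661, abs=5e-5)

    @pytest.mark.parametrize(
        "hits,n,K,U",
        [(-1, 3, 5, 20), (4, 3, 5, 20), (6, 10, 5, 20), (3, 25, 5, 20),
         (0, 0, 5, 20), (1, 3, 21, 20)],
    )
    def test_bound_violations_raise(self, hits, n, K, U):
        with pytest.raises(ValueError):
            fisher_prefix_p(hits, n, K, U)


class TestPrefixProfile:
    def test_disjoint_category_is_flat_and_flagged_free(self, ten_gene_list,
                                                        ten_gene_universe):
        prof = prefix_profile(ten_gene_list, {"ZZZ"}, ten_gene_universe)
        assert prof.t == 1.0
        assert prof.n_star == 1

    def test_top_pair_peaks_at_two(self, ten_gene_list, ten_gene_universe):
        prof = prefix_profile(ten_gene_list, {"G01", "G02"}, ten_gene_universe)
        assert prof.t == pytest.approx(1 / 45, rel=1e-12)
        assert prof.n_star == 2

    def test_members_at_bottom_peak_at_full_list(self, ten_gene_list):
        universe = {f"G{i:02d}" for i in range(1, 21)}
        prof = prefix_profile(ten_gene_list, {"G09", "G10"}, universe)
        exact, n_star = naive_full_scan(ten_gene_list, {"G09", "G10"}, universe)
        assert prof.n_star == n_star == 10
        assert prof.t == pytest.approx(float(exact), rel=1e-12)

    def test_saturated_profile_peaks_at_rank_one(self, ten_gene_list,
                                                 ten_gene_universe):
        # universe == list: every prefix probability saturates at 1
        prof = prefix_profile(ten_gene_list, {"G09", "G10"}, ten_gene_universe)
        assert prof.t == 1.0
        assert prof.n_star == 1

    def test_hits_counter_monotone_and_bounded(self, ten_gene_list,
                                               ten_gene_universe):
        prof = prefix_profile(ten_gene_list, {"G02", "G05", "G07"},
                              ten_gene_universe, full_scan=True)
        assert np.all(np.diff(prof.hits_at_n) >= 0)
        assert np.all(prof.hits_at_n <= np.minimum(prof.n, prof.K))
        assert np.all((prof.f > 0) & (prof.f <= 1))
        assert prof.t <= prof.f[-1]

    def test_ranked_gene_outside_universe_is_error(self, ten_gene_list):
        with pytest.raises(ValueError, match="absent from the universe"):
            prefix_profile(ten_gene_list, {"G01"}, {"G01", "G02"})

    @pytest.mark.parametrize("seed", range(12))
    def test_hit_position_scan_equals_exact_full_scan(self, seed):
        """Evaluating only where members enter reproduces the global scan."""
        rng = np.random.default_rng(seed)
        U = int(rng.integers(10, 50))
        N = int(rng.integers(2, min(30, U) + 1))
        K = int(rng.integers(1, 11))
        ids = [f"G{i:03d}" for i in range(U)]
        universe = set(ids)
        category = set(rng.choice(ids, size=min(K, U), replace=False))
        ranked = make_list(rng.choice(ids, size=N, replace=False))
        prof = prefix_profile(ranked, category, universe)
        exact_t, exact_n = naive_full_scan(ranked, category, universe)
        assert prof.n_star == exact_n
        assert prof.t == pytest.approx(float(exact_t), rel=1e-12)

    def test_appending_noise_genes_never_weakens_the_peak(self):
        """Padding the bottom of the list leaves hits intact, t non-increasing."""
        rng = np.random.default_rng(21)
        ids = [f"G{i:03d}" for i in range(60)]
        universe = set(ids)
        category = set(ids[:8])
        short = make_list(ids[:20])
        longer = make_list(ids[:35])  # 15 extra genes, none in the category
        p_short = prefix_profile(short, category, universe, full_scan=True)
        p_long = prefix_profile(longer, category, universe, full_scan=True)
        np.testing.assert_array_equal(p_short.hits_at_n,
                                      p_long.hits_at_n[: short.N])
        assert p_long.t <= p_short.t


class TestMinPStatistic:
    def _profile(self, ns, fs):
        ns = np.asarray(ns)
        fs = np.asarray(fs, dtype=float)
        return PrefixEnrichmentProfile(
            category="X", N=int(ns[-1]), n=ns, f=fs,
            hits_at_n=np.ones_like(ns), t=float(fs.min()),
            n_star=int(ns[np.argmin(fs)]), K=1, U=100,
        )

    def test_constant_profile_ties_to_smallest_n(self):
        assert min_p_statistic(self._profile([1, 5, 9], [1.0, 1.0, 1.0])) == (1.0, 1)

    def test_tied_minimum_reports_smallest_argmin(self):
        prof = self._profile([1, 4, 9], [0.3, 0.02, 0.02])
        assert min_p_statistic(prof) == (0.02, 4)

    def test_equals_enumeration_on_random_profiles(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fs = rng.uniform(0.001, 1.0, size=8)
            prof = self._profile(np.arange(1, 9), fs)
            t, n_star = min_p_statistic(prof)
            pairs = list(zip(fs, np.arange(1, 9)))
            t_exp = min(f for f, _ in pairs)
            n_exp = min(n for f, n in pairs if f == t_exp)
            assert (t, n_star) == (t_exp, n_exp)


class TestPermutationNull:
    def test_fixed_seed_is_bit_identical(self, ten_gene_list, ten_gene_universe):
        a = permutation_null(ten_gene_list, {"G01", "G05"}, ten_gene_universe,
                             B=50, seed=11)
        b = permutation_null(ten_gene_list, {"G01", "G05"}, ten_gene_universe,
                             B=50, seed=11)
        np.testing.assert_array_equal(a.t0, b.t0)

    def test_full_set_probability_is_permutation_invariant(
        self, ten_gene_list, ten_gene_universe
    ):
        category = {"G02", "G06", "G09"}
        obs = prefix_profile(ten_gene_list, category, ten_gene_universe)
        f_N_obs = obs.f[obs.n == obs.N][0]
        rng = np.random.default_rng(4)
        for _ in range(25):
            shuf = permute_ranking(ten_gene_list, rng)
            prof = prefix_profile(shuf, category, ten_gene_universe)
            assert prof.f[prof.n == prof.N][0] == f_N_obs

    def test_null_statistics_match_exhaustive_position_enumeration(
        self, ten_gene_list, ten_gene_universe
    ):
        """t0 for a 2-member category on 10 ranks has C(10,2)=45 equally
        likely configurations; the sampled distribution must match the
        enumerated one."""
        category = {"G03", "G07"}
        # exact distribution over all position pairs
        support = {}
        for p1, p2 in itertools.combinations(range(1, 11), 2):
            t = min(fisher_prefix_p(1, p1, 2, 10), fisher_prefix_p(2, p2, 2, 10))
            support[round(t, 12)] = support.get(round(t, 12), 0) + 1
        B = 4500
        null = permutation_null(ten_gene_list, category, ten_gene_universe,
                                B=B, seed=5)
        observed = {}
        for t in null.t0:
            observed[round(t, 12)] = observed.get(round(t, 12), 0) + 1
        assert set(observed) <= set(support)
        for t_val, count in support.items():
            p = count / 45
            expect = B * p
            sd = np.sqrt(B * p * (1 - p))
            assert abs(observed.get(t_val, 0) - expect) < 5 * sd + 1

    def test_position_sampling_matches_explicit_gene_permutation(
        self, ten_gene_list, ten_gene_universe
    ):
        """The fast null (uniform hit-position subsets) and the literal
        route (shuffle the gene vector, rescan) draw from the same law."""
        from scipy.stats import ks_2samp

        category = {"G01", "G04", "G08"}
        fast = permutation_null(ten_gene_list, category, ten_gene_universe,
                                B=800, seed=6)
        rng = np.random.default_rng(6)
        literal = np.array([
            prefix_profile(permute_ranking(ten_gene_list, rng), category,
                           ten_gene_universe).t
            for _ in range(800)
        ])
        assert ks_2samp(fast.t0, literal).pvalue > 1e-3

    def test_resample_genome_model_varies_hit_count(self, ten_gene_list):
        ids = [f"G{i:02d}" for i in range(1, 41)]
        universe = set(ids)
        ranked = make_list(ids[:10])
        null = permutation_null(ranked, set(ids[:6]), universe, B=300, seed=7,
                                null_model="resample-genome")
        # with K=6 of U=40 and N=10 draws, zero-hit lists occur sometimes
        assert np.any(null.t0 == 1.0)
        assert np.any(null.t0 < 1.0)

    def test_invalid_b_rejected(self, ten_gene_list, ten_gene_universe):
        with pytest.raises(ValueError, match="B"):
            permutation_null(ten_gene_list, {"G01"}, ten_gene_universe, B=0)


class TestEmpiricalEValue:
    def _null(self, t0):
        t0 = np.asarray(t0, dtype=float)
        return NullDistribution(t0=t0, B=len(t0), seed=0, category="X",
                                direction="up")

    def test_statistic_below_all_nulls(self):
        null = self._null(np.linspace(0.5, 1.0, 1000))
        assert empirical_e_value(1e-6, null) == pytest.approx(1 / 1001)

    def test_statistic_above_all_nulls(self):
        null = self._null(np.linspace(0.001, 0.9, 1000))
        assert empirical_e_value(0.95, null) == 1.0

    def test_statistic_at_median_of_odd_null(self):
        B = 101
        t0 = np.linspace(0.01, 0.99, B)
        e = empirical_e_value(np.median(t0), null=self._null(t0))
        assert e == pytest.approx((1 + (B + 1) // 2) / (B + 1))

    def test_smaller_t_never_increases_e(self):
        null = self._null(np.random.default_rng(0).uniform(size=200))
        es = [empirical_e_value(t, null) for t in np.linspace(0, 1, 50)]
        assert all(a <= b for a, b in zip(es, es[1:]))


def naive_bh(p):
    """Step-up closed form: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_step_up_closed_form(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, naive_bh(p), rtol=1e-12, atol=1e-15)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestRunIdea:
    def _setup(self, rng, U=400, N=60, n_cat=4, k=15):
        ids = [f"G{i:04d}" for i in range(U)]
        universe = set(ids)
        cats = {
            f"C{j}": set(rng.choice(ids, size=k, replace=False))
            for j in range(n_cat)
        }
        collection = GeneSetCollection(cats, universe)
        ranked = make_list(rng.choice(ids, size=N, replace=False))
        return ranked, collection

    def test_disjoint_category_reports_no_signal(self, ten_gene_list,
                                                 ten_gene_universe):
        collection = GeneSetCollection(
            {"FAR": {"G01", "G02"}, "NOWHERE": set()},
            ten_gene_universe | {"X1", "X2", "X3"},
        )
        collection.categories["NOWHERE"] = {"X1", "X2", "X3"}
        res = run_idea(ten_gene_list, collection, B=100, seed=3)
        row = res[res["category"] == "NOWHERE"].iloc[0]
        assert row["t_min_fisher_p"] == 1.0
        assert row["e_value"] > 0.9
        assert row["driver_genes"] == ""

    def test_results_deterministic_and_order_independent(self):
        rng = np.random.default_rng(10)
        ranked, collection = self._setup(rng)
        res1 = run_idea(ranked, collection, B=120, seed=42)
        # present the categories in reversed insertion order
        rev = GeneSetCollection(
            dict(reversed(list(collection.categories.items()))),
            collection.universe,
        )
        res2 = run_idea(ranked, rev, B=120, seed=42)
        assert res1.equals(res2)

    def test_rows_sorted_by_e_value_then_name(self):
        rng = np.random.default_rng(12)
        ranked, collection = self._setup(rng)
        res = run_idea(ranked, collection, B=80, seed=1)
        keys = list(zip(res["e_value"], res["category"]))
        assert keys == sorted(keys)

    def test_driver_genes_consistent_with_peak(self):
        rng = np.random.default_rng(13)
        ranked, collection = self._setup(rng)
        res = run_idea(ranked, collection, B=80, seed=2)
        for _, row in res.iterrows():
            drivers = [g for g in row["driver_genes"].split(";") if g]
            assert len(drivers) == row["hits_at_peak"]
            members = collection.categories[row["category"]]
            prefix = ranked.genes[: row["n_star"]]
            assert drivers == [g for g in prefix if g in members]
            assert 1 <= row["n_star"] <= ranked.N
            assert 0 < row["e_value"] <= 1
            assert row["q_value"] >= row["e_value"] - 1e-15

    def test_empty_collection_warns_and_returns_empty(self, ten_gene_list,
                                                      ten_gene_universe, caplog):
        collection = GeneSetCollection({}, ten_gene_universe)
        with caplog.at_level("WARNING"):
            res = run_idea(ten_gene_list, collection, B=10, seed=0)
        assert res.empty

    def test_planted_block_hits_the_e_value_floor(self):
        """A category filling the top ranks beats every shuffle."""
        rng = np.random.default_rng(14)
        U, N, m = 2000, 200, 20
        ids = [f"G{i:05d}" for i in range(U)]
        members = ids[:m]
        rest = rng.choice(ids[m:], size=N - m, replace=False).tolist()
        ranked = make_list(members + rest)
        collection = GeneSetCollection({"PLANTED": set(members)}, set(ids))
        res = run_idea(ranked, collection, B=199, seed=9)
        row = res.iloc[0]
        assert row["e_value"] == pytest.approx(1 / 200)
        assert row["n_star"] == m
        assert row["t_min_fisher_p"] == pytest.approx(
            fisher_prefix_p(m, m, m, U), rel=1e-12
        )
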