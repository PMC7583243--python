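import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from rookery.seqdata import Alignment, encode_sequences
from rookery import sumstats as ss


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

class TestHaplotypeDiversity:
    @pytest.mark.parametrize("counts, expected", [
        ([10], 0.0),                  # all identical
        ([1] * 10, 1.0),              # all distinct: n(1-1/n)/(n-1) = 1
        ([5, 3, 2], 0.68889),         # hand evaluation of Nei's formula
    ])
    def test_known_values(self, counts, expected):
        assert ss.haplotype_diversity(counts) == pytest.approx(expected,
                                                               abs=1e-5)

    def test_undefined_below_two(self):
        assert np.isnan(ss.haplotype_diversity([1]))

    @given(st.lists(st.integers(1, 20), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_relabelling(self, counts):
        rng = np.random.default_rng(0)
        perm = rng.permutation(counts)
        assert ss.haplotype_diversity(counts) == pytest.approx(
            ss.haplotype_diversity(perm))


class TestNucleotideDiversity:
    def test_single_difference(self):
        mat = encode_sequences(["AAAAAAAAAA", "AAAAAAAAAT"])
        assert ss.nucleotide_diversity(mat) == pytest.approx(0.1)

    def test_identical(self):
        assert ss.nucleotide_diversity(encode_sequences(["ACGT"] * 3)) == 0.0

    def test_matches_bruteforce_pair_enumeration(self, toy):
        seqs = toy["pi_seqs"]
        mat = encode_sequences(seqs)
        pairs = list(itertools.combinations(range(len(seqs)), 2))
        expected = np.mean([
            sum(a != b for a, b in zip(seqs[i], seqs[j])) / len(seqs[i])
            for i, j in pairs])
        assert ss.nucleotide_diversity(mat) == pytest.approx(expected)

    def test_pairwise_complete_handles_missing(self):
        # pair (0,1): one diff over the 4 sites where both carry a base
        mat = encode_sequences(["ACGTN", "ACCT-"])
        prop, diffs, comps = ss.pairwise_distance_matrix(mat)
        assert comps[0, 1] == 4
        assert diffs[0, 1] == 1
        assert prop[0, 1] == pytest.approx(1 / 4)

    def test_no_comparable_sites_is_error(self):
        mat = encode_sequences(["ANNN", "NAAA"])
        with pytest.raises(ValueError, match="comparable"):
            ss.pairwise_distance_matrix(mat)


# ---------------------------------------------------------------------------
# AMOVA F_ST
# ---------------------------------------------------------------------------

def _oracle_flat_amova(counts):
    """Literal sums-of-squares AMOVA on expanded individuals, identity
    distance; an independent, loop-based route."""
    counts = np.asarray(counts)
    inds = []   # (haplotype, unit)
    for h in range(counts.shape[0]):
        for u in range(counts.shape[1]):
            inds += [(h, u)] * counts[h, u]
    n = len(inds)
    pops = sorted({u for _, u in inds})
    d2 = np.array([[0.0 if hi == hj else 1.0 for hj, _ in inds]
                   for hi, _ in inds])
    ssd_t = d2.sum() / (2.0 * n)
    ssd_w = 0.0
    sizes = []
    for p in pops:
        ix = [k for k, (_, u) in enumerate(inds) if u == p]
        sizes.append(len(ix))
        ssd_w += d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix))
    df_a, df_w = len(pops) - 1, n - len(pops)
    sigma_w = ssd_w / df_w
    n_bar = (n - sum(s ** 2 for s in sizes) / n) / df_a
    sigma_a = ((ssd_t - ssd_w) / df_a - sigma_w) / n_bar
    return sigma_a / (sigma_a + sigma_w)


class TestAmovaFst:
    def test_fixed_different_haplotypes_is_one(self):
        assert ss.fst_from_counts([[5, 0], [0, 5]]) == pytest.approx(1.0)

    def test_identical_frequency_vectors_not_positive(self):
        assert ss.fst_from_counts([[3, 3], [2, 2]]) <= 0.0

    def test_monomorphic_pair_undefined(self):
        assert np.isnan(ss.fst_from_counts([[4, 6]]))

    @pytest.mark.parametrize("counts", [
        [[6, 1], [2, 5], [0, 3]],
        [[10, 2], [1, 9]],
        [[3, 0, 1], [1, 4, 2], [2, 2, 5]],
    ])
    def test_matches_sums_of_squares_oracle(self, counts):
        assert ss.fst_from_counts(counts) == pytest.approx(
            _oracle_flat_amova(counts))

    def test_frequency_equals_distance_mode_for_equidistant_haplotypes(self):
        # every distinct haplotype pair differs at exactly 2 sites
        base = "A" * 8
        hap = {0: base, 1: "T" + base[1:-1] + "T", 2: "G" + base[1:-1] + "G"}
        assign = [0, 0, 0, 1, 1, 2, 0, 1, 2, 2]
        units = ["u1"] * 5 + ["u2"] * 5
        ids = [f"s{i}" for i in range(10)]
        labels = pd.DataFrame({"level1": units, "level2": pd.NA,
                               "level3": pd.NA}, index=ids)
        a = Alignment(ids, [hap[h] for h in assign], labels)
        a.unit_order = {1: ["u1", "u2"]}
        from rookery.seqdata import collapse_haplotypes
        f_freq = ss.amova_fst(collapse_haplotypes(a, 1), mode="frequency")
        f_dist = ss.amova_fst(a, 1, mode="distance")
        assert f_freq == pytest.approx(f_dist, abs=1e-12)

    def test_permutation_pvalue_detects_structure(self):
        counts = np.array([[20, 0], [0, 20]])
        f, p = ss.amova_fst(counts, mode="frequency", n_perm=199, seed=3)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_seed_required_for_permutations(self):
        with pytest.raises(ValueError, match="seed"):
            ss.amova_fst(np.array([[2, 1], [1, 2]]), mode="frequency",
                         n_perm=10)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_degenerate_single_haplotype(self):
        assert ss.exact_differentiation_test([[10, 10]]) == 1.0

    def test_fully_differentiated_table(self, toy):
        p = ss.exact_differentiation_test(toy["contingency_2x2"],
                                          chain_len=20000, burnin=2000,
                                          seed=0)
        assert p < 0.001
        assert ss.enumerate_exact_test(toy["contingency_2x2"]) < 0.001

    @pytest.mark.parametrize("table", [
        [[6, 2], [3, 5]], [[4, 4], [4, 4]], [[7, 1], [2, 6]],
    ])
    def test_enumeration_agrees_with_fisher(self, table):
        """For 2x2 tables the exhaustive oracle must equal Fisher's exact
        two-sided p (identical tail definition)."""
        assert ss.enumerate_exact_test(np.array(table)) == pytest.approx(
            fisher_exact(table)[1], abs=1e-10)

    @pytest.mark.parametrize("table", [
        [[6, 2], [3, 5], [1, 4]],
        [[5, 1], [2, 4], [1, 1], [0, 2]],
        [[3, 3], [3, 3], [3, 3]],
    ])
    def test_markov_chain_converges_to_enumeration(self, table):
        table = np.array(table)
        truth = ss.enumerate_exact_test(table)
        ests = [ss.exact_differentiation_test(table, chain_len=60000,
                                              burnin=6000, seed=s)
                for s in (1, 2, 3)]
        # MC standard error of the chain fraction, inflated for
        # autocorrelation; 3 seeds must all be within it
        se = 3 * np.sqrt(truth * (1 - truth) / 60000) * 6 + 0.01
        for e in ests:
            assert abs(e - truth) < se


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

def _two_cluster_alignment(seed=0):
    """Four units in two diverged clusters; each cluster segregates a small
    shared haplotype pool (so identity-distance AMOVA can see the clusters)."""
    rng = np.random.default_rng(seed)
    base1 = rng.integers(0, 4, 40, dtype=np.uint8)
    base2 = base1.copy()
    base2[:12] = (base2[:12] + 1) % 4
    pools = []
    for base in (base1, base2):
        pool = [base]
        for site in (20, 30):
            v = base.copy()
            v[site] = (v[site] + 1) % 4
            pool.append(v)
        pools.append(pool)
    seqs, units = [], []
    for ui, pool in enumerate([pools[0], pools[0], pools[1], pools[1]]):
        for _ in range(8):
            h = rng.choice(3, p=[0.6, 0.3, 0.1])
            seqs.append("".join("ACGT"[c] for c in pool[h]))
            units.append(f"u{ui}")
    ids = [f"s{i}" for i in range(len(seqs))]
    labels = pd.DataFrame({"level1": units, "level2": pd.NA, "level3": pd.NA},
                          index=ids)
    a = Alignment(ids, seqs, labels)
    a.unit_order = {1: ["u0", "u1", "u2", "u3"]}
    return a


class TestHierarchicalAmova:
    def test_correct_grouping_detects_structure(self):
        a = _two_cluster_alignment()
        res = ss.hierarchical_amova(a, {"g1": ["u0", "u1"],
                                        "g2": ["u2", "u3"]}, 1,
                                    n_perm=199, seed=5)
        assert res.f_ct > 0.3
        # permuting 4 units over 2 groups has only 6 distinct outcomes, so
        # the best achievable p is bounded; just require enrichment
        assert res.p_fct < 0.5

    def test_misgrouping_gives_small_fct(self):
        a = _two_cluster_alignment()
        res = ss.hierarchical_amova(a, {"g1": ["u0", "u2"],
                                        "g2": ["u1", "u3"]}, 1, n_perm=0)
        assert res.f_ct < 0.1

    def test_components_sum_matches_flat_total_variance(self):
        a = _two_cluster_alignment()
        res = ss.hierarchical_amova(a, {"g1": ["u0", "u1"],
                                        "g2": ["u2", "u3"]}, 1, n_perm=0)
        from rookery.seqdata import collapse_haplotypes
        ht = collapse_haplotypes(a, 1)
        sigma_a, sigma_w = ss._flat_amova_from_counts(ht.counts)
        total_flat = sigma_a + sigma_w
        total_hier = res.sigma_a + res.sigma_b + res.sigma_c
        assert total_hier == pytest.approx(total_flat, rel=0.15)

    def test_single_group_is_error(self):
        a = _two_cluster_alignment()
        with pytest.raises(ValueError, match="two groups"):
            ss.hierarchical_amova(a, {"g": ["u0", "u1", "u2", "u3"]}, 1)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

class TestMantel:
    def test_self_correlation_is_one(self, toy):
        r, p = ss.mantel_test(toy["mantel_d1"], toy["mantel_d1"],
                              n_perm=499, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_independent_matrices_null(self):
        rng = np.random.default_rng(4)
        n = 8
        x = rng.normal(size=(n, n)); x = np.abs(x + x.T); np.fill_diagonal(x, 0)
        y = rng.normal(size=(n, n)); y = np.abs(y + y.T); np.fill_diagonal(y, 0)
        r, p = ss.mantel_test(x, y, n_perm=499, seed=1)
        assert abs(r) < 0.5 and p > 0.05

    def test_r_equals_direct_formula(self, toy):
        d1, d2 = toy["mantel_d1"], toy["mantel_d2"]
        iu = np.triu_indices(5, 1)
        x, y = d1[iu], d2[iu]
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        r, _ = ss.mantel_test(d1, d2, n_perm=99, seed=0)
        assert r == pytest.approx(expected)

    def test_constant_matrix_undefined(self):
        c = np.ones((5, 5)); np.fill_diagonal(c, 0)
        r, p = ss.mantel_test(c, np.arange(25.).reshape(5, 5), n_perm=99,
                              seed=0)
        assert np.isnan(r)

    def test_too_few_units(self):
        with pytest.raises(ValueError, match="4"):
            ss.mantel_test(np.zeros((3, 3)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli
# ---------------------------------------------------------------------------

class TestBenjaminiYekutieli:
    def test_single_test_reduces_to_alpha(self):
        sig, thr = ss.benjamini_yekutieli_adjust([0.04], 0.05)
        assert sig.tolist() == [True] and thr == pytest.approx(0.05)
        sig, _ = ss.benjamini_yekutieli_adjust([0.06], 0.05)
        assert sig.tolist() == [False]

    def test_all_ones_nothing_significant(self):
        sig, thr = ss.benjamini_yekutieli_adjust([1.0] * 5, 0.05)
        assert not sig.any() and thr == 0.0

    def test_three_test_pattern_hand_computed(self):
        # c(3) = 1.8333; step-up thresholds 0.00909, 0.01818, 0.02727
        sig, thr = ss.benjamini_yekutieli_adjust([0.001, 0.02, 0.5], 0.05)
        assert sig.tolist() == [True, False, False]
        assert thr == pytest.approx(0.05 / (3 * (1 + 1 / 2 + 1 / 3)))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_statsmodels_fdr_by(self, pvals):
        from statsmodels.stats.multitest import multipletests
        ours, _ = ss.benjamini_yekutieli_adjust(pvals, 0.05)
        theirs = multipletests(pvals, alpha=0.05, method="fdr_by")[0]
        assert ours.tolist() == theirs.tolist()


# ---------------------------------------------------------------------------
# Battery on the study-shaped fixture
# ---------------------------------------------------------------------------

class TestPairwiseBattery:
    def test_fixture_battery_shapes_and_symmetry(self, small_fixture):
        res = ss.pairwise_differentiation(small_fixture, 2, n_perm=99,
                                          exact_chain_len=3000,
                                          exact_burnin=500, seed=0)
        k = len(res.unit_names)
        assert res.fst.shape == (k, k)
        assert np.allclose(res.fst, res.fst.T)
        assert np.all(np.diag(res.fst) == 0)
        assert ((res.p_perm >= 0) & (res.p_perm <= 1)).all()
        # the haplogroup-II island must stand out most
        sv = res.unit_names.index("SaoVicente")
        means = np.array([np.delete(np.maximum(res.fst[i], 0), i).mean()
                          for i in range(k)])
        assert means.argmax() == sv

    def test_diversity_table_invariants(self, small_fixture):
        t = ss.diversity_table(small_fixture, 2)
        assert (t["nHap"] <= t["n"]).all()
        assert ((t["Hd"] >= 0) & (t["Hd"] <= 1)).all()
        assert (t["pi"] >= 0).all()
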