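"""Diversity statistics against hand calculations and independent oracles
(scikit-bio / scipy brute force)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from endopan.diversity import (
    DistanceMatrix,
    alpha_diversity,
    alpha_diversity_table,
    bray_curtis,
    group_tests,
    nmds,
    pcoa,
    permanova,
    rarefaction_curve,
    rarefaction_expected,
)
from endopan.simulate import SimConfig, simulate_communities


class TestAlpha:
    def test_uniform_shannon(self):
        assert alpha_diversity([5, 5, 5, 5], "shannon") == pytest.approx(math.log(4))

    def test_single_taxon(self):
        assert alpha_diversity([7], "shannon") == 0.0
        assert alpha_diversity([7], "simpson") == 0.0

    def test_chao1_hand_value(self):
        # S=4, F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
        assert alpha_diversity([1, 1, 2, 3], "chao1") == 4.5

    def test_indices_match_scikit_bio(self):
        from skbio.diversity.alpha import ace, chao1, shannon, simpson

        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=rng.integers(3, 15))
            if counts.sum() == 0 or (counts > 0).sum() < 2:
                continue
            assert alpha_diversity(counts, "shannon") == pytest.approx(
                shannon(counts, base=np.e), rel=1e-9)
            assert alpha_diversity(counts, "simpson") == pytest.approx(
                simpson(counts), rel=1e-9)
            assert alpha_diversity(counts, "chao1") == pytest.approx(
                chao1(counts, bias_corrected=True), rel=1e-9)
            rare = counts[(counts > 0) & (counts <= 10)]
            if len(rare) and (rare == 1).sum() != len(rare):
                assert alpha_diversity(counts, "ace") == pytest.approx(
                    ace(counts, rare_threshold=10), rel=1e-9)

    def test_estimators_bound_observed_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 20, size=10)
            if counts.sum() == 0:
                continue
            s_obs = (counts > 0).sum()
            assert alpha_diversity(counts, "chao1") >= s_obs
            assert alpha_diversity(counts, "ace") >= s_obs - 1e-9

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0], "shannon")


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        curve = rarefaction_curve([4, 4, 2], depths=[10], reps=5)
        assert curve.iloc[0] == 3.0

    def test_depth_one(self):
        curve = rarefaction_curve([4, 4, 2], depths=[1], reps=5)
        assert curve.iloc[0] == 1.0

    def test_subsampling_matches_hypergeometric_closed_form(self):
        expected = rarefaction_expected([4, 4, 2], 5)
        curve = rarefaction_curve([4, 4, 2], depths=[5], reps=5000, seed=0)
        assert curve.iloc[0] == pytest.approx(expected, abs=0.05)

    def test_excess_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 2], depths=[5], reps=2)

    def test_expectation_monotone_in_depth(self):
        counts = [9, 5, 3, 1, 1]
        values = [rarefaction_expected(counts, d) for d in range(1, 20)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = pd.DataFrame({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0],
                          "c": [0, 0, 3, 1]})
        dm = bray_curtis(t)
        frame = dm.to_frame()
        assert frame.loc["a", "b"] == 0.0
        assert frame.loc["a", "c"] == 1.0

    def test_hand_value(self):
        dm = bray_curtis(pd.DataFrame({"x": [2, 1], "y": [1, 3]}))
        assert dm.values[0, 1] == pytest.approx(3 / 7)

    def test_properties_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = pd.DataFrame(rng.integers(0, 50, size=(8, 5)) + 1)
            dm = bray_curtis(t)
            assert np.allclose(dm.values, dm.values.T)
            assert np.all(np.diag(dm.values) == 0)
            assert dm.values.min() >= 0 and dm.values.max() <= 1

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.integers(1, 100, size=(6, 4)))
        dm = bray_curtis(t)
        for i, j in itertools.combinations(range(4), 2):
            assert dm.values[i, j] == pytest.approx(
                braycurtis(t.iloc[:, i], t.iloc[:, j]), rel=1e-12)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1], "b": [0]}))


class TestPcoa:
    def test_two_samples_unit_distance(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), labels=["a", "b"])
        coords, eigvals = pcoa(dm)
        assert sorted(np.abs(coords.iloc[:, 0])) == pytest.approx([0.5, 0.5])
        assert (eigvals > 1e-12).sum() == 1

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        d = cdist(pts, pts)
        coords, _ = pcoa(DistanceMatrix(d, labels=[str(i) for i in range(7)]))
        rec = cdist(coords.values[:, :2], coords.values[:, :2])
        assert np.allclose(rec, d, atol=1e-9)

    def test_matches_scikit_bio_eigenvalues(self):
        import skbio

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = cdist(pts, pts)
        _, eigvals = pcoa(DistanceMatrix(d, labels=list("abcdef")))
        sk = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d, ids=list("abcdef")))
        assert np.allclose(sorted(eigvals, reverse=True)[:5],
                           sorted(sk.eigvals.values, reverse=True)[:5], atol=1e-9)


class TestNmds:
    def test_exact_embedding_reaches_tiny_stress(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
        d = cdist(pts, pts)
        _, stress = nmds(DistanceMatrix(d, labels=list("abc")), seed=0, n_starts=10)
        assert stress < 1e-4

    def test_shepard_correlation_on_planar_points(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 2))
        d = cdist(pts, pts)
        coords, stress = nmds(DistanceMatrix(d, labels=[str(i) for i in range(10)]),
                              seed=0)
        rec = cdist(coords.values, coords.values)
        iu = np.triu_indices(10, 1)
        r = np.corrcoef(d[iu], rec[iu])[0, 1]
        assert r > 0.99

    def test_degenerate_input_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="degenerate"):
            nmds(DistanceMatrix(d, labels=list("abcd")))


def _brute_force_pseudo_f(d, groups):
    """Independent loop-based pseudo-F for the permutation oracle."""
    n = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(set(groups))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(7, 3))
        d = cdist(pts, pts)
        groups = ["x", "x", "x", "x", "y", "y", "y"]
        dm = DistanceMatrix(d, labels=[str(i) for i in range(7)])
        f, p = permanova(dm, groups, exhaustive="always")
        # oracle: enumerate all distinct label arrangements independently
        f_obs = _brute_force_pseudo_f(d, groups)
        assert f == pytest.approx(f_obs, rel=1e-9)
        ge = total = 0
        for combo in itertools.combinations(range(7), 4):
            arrangement = ["x" if i in combo else "y" for i in range(7)]
            total += 1
            ge += _brute_force_pseudo_f(d, arrangement) >= f_obs - 1e-12
        assert p == pytest.approx(ge / total, rel=1e-9)

    def test_statistic_matches_scikit_bio(self):
        import skbio
        from skbio.stats.distance import permanova as skperm

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 2))
        d = cdist(pts, pts)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, _ = permanova(DistanceMatrix(d, labels=[str(i) for i in range(9)]),
                         groups, n_perm=9, seed=0)
        sk = skperm(skbio.DistanceMatrix(d, ids=[str(i) for i in range(9)]),
                    grouping=groups, permutations=9)
        assert f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_identical_groups_give_f_zero_p_one(self):
        # points A1,B1 (group 1) coincide with A2,B2 (group 2): d(A*,B*)=1,
        # d(A1,A2)=d(B1,B2)=0, order A1,B1,A2,B2
        d = np.array([[0.0, 1.0, 0.0, 1.0],
                      [1.0, 0.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0, 1.0],
                      [1.0, 0.0, 1.0, 0.0]])
        dm = DistanceMatrix(d, labels=list("abcd"))
        f, p = permanova(dm, ["g1", "g1", "g2", "g2"], exhaustive="always")
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_relabeling_within_groups_preserves_p(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        d = cdist(pts, pts)
        labels = [str(i) for i in range(6)]
        dm = DistanceMatrix(d, labels=labels)
        f1, p1 = permanova(dm, ["u", "u", "u", "v", "v", "v"], exhaustive="always")
        f2, p2 = permanova(dm, ["q", "q", "q", "w", "w", "w"], exhaustive="always")
        assert (f1, p1) == (f2, p2)

    def test_empty_group_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), labels=["a", "b"])
        with pytest.raises(ValueError):
            permanova(dm, ["g", "g"])


class TestGroupTests:
    def test_identical_groups(self):
        t, p = group_tests([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, "welch_t")
        assert t == 0.0 and p == pytest.approx(1.0)
        f, _ = group_tests([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, "anova")
        assert f == pytest.approx(0.0)

    def test_welch_matches_formula_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        t, p = group_tests(x + y, ["a"] * 4 + ["b"] * 4, "welch_t")
        # independent evaluation of the Welch formulas
        mx, my = np.mean(x), np.mean(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        se2 = vx / 4 + vy / 4
        t_ref = (mx - my) / math.sqrt(se2)
        df_ref = se2 ** 2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)
        sp = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(sp.statistic, rel=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-12)

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(10)
        groups = ["a"] * 5 + ["b"] * 4 + ["c"] * 6
        values = rng.normal(size=15) + np.array([0] * 5 + [1] * 4 + [0.5] * 6)
        f, p = group_tests(values, groups, "anova")
        sp = stats.f_oneway(values[:5], values[5:9], values[9:])
        assert f == pytest.approx(sp.statistic, rel=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-12)

    def test_insufficient_sizes_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1, 2, 3], ["a", "a", "b"], "welch_t")


class TestTissueContrast:
    def test_root_leaf_shannon_difference_detected_with_power(self):
        """Welch's t on per-sample Shannon separates root from leaf tissue
        in >= 80% of simulated communities at alpha = 0.05."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_taxa_pool=150, depth_per_sample=8000)
            table, _ = simulate_communities(cfg)
            alpha = alpha_diversity_table(table, ["shannon"])
            tissue = ["leaf" if s.endswith("L") else "root" for s in alpha.index]
            _, p = group_tests(alpha["shannon"], tissue, "welch_t")
            hits += p < 0.05
        assert hits >= 0.8 * n_seeds
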