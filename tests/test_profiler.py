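"""Profiling filters, TMM, diversity metrics, rarefaction, Stokes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycometer import profiler
from mycometer.profiler import (Hit, SedimentationParams, alpha_diversity,
                                bray_curtis, depth_profile_to_abundance,
                                lineage_tree, stokes_solve, tmm_normalize,
                                weighted_unifrac)


class TestDepthProfile:
    def test_depth_filter_boundary_15_vs_14(self):
        hits = [Hit("gA", 30, "sp1"), Hit("gB", 14, "sp2"), Hit("gC", 30, "sp1")]
        prof = depth_profile_to_abundance(hits, min_depth=15)
        assert prof.abundances == {"sp1": 1.0}
        keep = depth_profile_to_abundance(
            [Hit("gA", 30, "sp1"), Hit("gB", 15, "sp2")], min_depth=15)
        assert keep.abundances["sp2"] == pytest.approx(15 / 45)

    def test_normalization_without_filtering(self):
        hits = [Hit("a", 30, "sp1"), Hit("b", 10, "sp2")]
        prof = depth_profile_to_abundance(hits, min_depth=0)
        assert prof.abundances == pytest.approx({"sp1": 0.75, "sp2": 0.25})

    def test_off_target_pooling(self):
        hits = [Hit("a", 40, "sp1"), Hit("b", 40, "sp1"), Hit("c", 20, "sp3")]
        prof = depth_profile_to_abundance(hits, 0, expected_taxa={"sp1"})
        assert prof.off_target_mass == pytest.approx(0.2)
        assert prof.abundances == pytest.approx({"sp1": 0.8})

    def test_genus_aggregation(self):
        hits = [Hit("a", 30, "sp1", "gen1"), Hit("b", 30, "sp2", "gen1"),
                Hit("c", 40, "sp3", "gen2")]
        prof = depth_profile_to_abundance(hits, 0, level="genus")
        assert prof.abundances == pytest.approx({"gen1": 0.6, "gen2": 0.4})

    def test_all_filtered_errors(self):
        with pytest.raises(ValueError, match="depth filter"):
            depth_profile_to_abundance([Hit("a", 5, "sp1")], min_depth=15)

    def test_profile_sums_to_one(self):
        rng = np.random.default_rng(0)
        hits = [Hit(f"g{i}", float(d), f"sp{i % 7}")
                for i, d in enumerate(rng.integers(1, 100, 30))]
        prof = depth_profile_to_abundance(hits, 10, expected_taxa={"sp0", "sp1"})
        assert sum(prof.abundances.values()) + prof.off_target_mass == pytest.approx(1.0)


class TestTMM:
    def test_identical_samples(self):
        c = pd.DataFrame([[10, 20, 30, 5]] * 2, index=["a", "b"]).astype(float)
        fac, _ = tmm_normalize(c)
        assert np.allclose(fac, 1.0)

    def test_pure_library_size_difference(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 100, 20).astype(float)
        c = pd.DataFrame([a, 2 * a], index=["A", "B"])
        fac, _ = tmm_normalize(c)
        assert np.allclose(fac, 1.0, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.negative_binomial(5, 0.05, (5, 100)).astype(float))
        fac, _ = tmm_normalize(c)
        assert np.exp(np.log(fac).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_edger_oracle(self):
        """Frozen oracle: edgeR::calcNormFactors(method='TMM') on the same
        matrix (negative binomial counts, rng PCG64 seed 42)."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(4, 200)).astype(float),
            index=[f"s{i}" for i in range(4)])
        fac, _ = tmm_normalize(counts)
        expected = [0.9942047, 0.9906499, 1.022424, 0.993054]
        assert np.allclose(fac.to_numpy(), expected, atol=1e-6)

    def test_brute_force_trimmed_mean_oracle(self):
        """Independent re-computation of the doubly trimmed weighted M-mean
        on a 20-feature toy."""
        rng = np.random.default_rng(3)
        a = rng.integers(5, 200, 20).astype(float)
        b = (a * rng.uniform(0.5, 2.0, 20)).round()
        c = pd.DataFrame([a, b], index=["A", "B"])
        fac, _ = tmm_normalize(c)
        # oracle: explicit sort-based trimming
        la, lb = a.sum(), b.sum()
        m = np.log2((b / lb) / (a / la))
        aa = 0.5 * np.log2((b / lb) * (a / la))
        n = len(m)
        keep = np.ones(n, bool)
        order_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        order_a = np.argsort(np.argsort(aa, kind="stable"), kind="stable")
        lo_m, hi_m = math.floor(n * 0.3), n - math.floor(n * 0.3) - 1
        lo_a, hi_a = math.floor(n * 0.05), n - math.floor(n * 0.05) - 1
        keep = (order_m >= lo_m) & (order_m <= hi_m) & \
               (order_a >= lo_a) & (order_a <= hi_a)
        w = (la - a) / (la * a) + (lb - b) / (lb * b)
        f_b = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected = pd.Series({"A": 1 / np.sqrt(f_b), "B": f_b / np.sqrt(f_b)})
        assert np.allclose(fac, expected, atol=1e-9)

    def test_disjoint_sample_warns_factor_one(self):
        c = pd.DataFrame([[5, 5, 0, 0, 5], [0, 0, 7, 0, 0], [4, 6, 0, 1, 5]],
                         index=["a", "b", "c"]).astype(float)
        with pytest.warns(UserWarning, match="no positive features"):
            fac, _ = tmm_normalize(c, ref_sample="a")


class TestAlphaDiversity:
    def test_uniform_profile_shannon(self):
        obs, sh, _ = alpha_diversity({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25})
        assert obs == 4
        assert sh == pytest.approx(math.log(4))

    def test_chao1_hand_formula(self):
        counts = [1, 1, 2, 5, 9]  # S=5, f1=2, f2=1
        assert alpha_diversity(counts)[2] == pytest.approx(7.0)

    def test_chao1_bias_corrected_when_no_doubletons(self):
        counts = [1, 1, 1, 5]  # S=4, f1=3, f2=0 -> 4 + 3*2/2 = 7
        assert alpha_diversity(counts)[2] == pytest.approx(7.0)

    def test_single_taxon(self):
        obs, sh, chao = alpha_diversity([7])
        assert (obs, sh, chao) == (1, 0.0, 1.0)

    def test_empty_sample_warns_zeros(self):
        with pytest.warns(UserWarning, match="empty"):
            assert alpha_diversity([0, 0]) == (0, 0.0, 0.0)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5}) == 0
        assert bray_curtis({"a": 1.0}, {"b": 1.0}) == 1

    def test_hand_value(self):
        assert bray_curtis({"x": 0.5, "y": 0.5}, {"x": 1.0}) == pytest.approx(0.5)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis({"a": 0.0}, {"b": 0.0})

    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=6),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, xs, ys):
        p = {f"t{i}": v for i, v in enumerate(xs)}
        q = {f"t{i}": v for i, v in enumerate(ys)}
        d = bray_curtis(p, q)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(q, p))


class TestWeightedUnifrac:
    def test_identity_zero(self):
        tree = lineage_tree({"a": ("F", "g1"), "b": ("F", "g2")})
        p = {"a": 0.3, "b": 0.7}
        assert weighted_unifrac(p, dict(p), tree) == 0

    def test_star_tree_disjoint_profiles(self):
        from skbio import TreeNode

        tree = TreeNode(name="root")
        for n in ("a", "b", "c"):
            tree.append(TreeNode(name=n, length=1.0))
        d = weighted_unifrac({"a": 1.0}, {"b": 1.0}, tree)
        assert d == pytest.approx(1.0)

    def test_star_tree_equals_half_l1(self):
        """On a star tree with unit branches, the normalized weighted UniFrac
        is L1/2 over total mass: checked against a brute-force branch sum."""
        from skbio import TreeNode

        rng = np.random.default_rng(4)
        names = [f"t{i}" for i in range(6)]
        tree = TreeNode(name="root")
        for n in names:
            tree.append(TreeNode(name=n, length=1.0))
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            got = weighted_unifrac(dict(zip(names, p)), dict(zip(names, q)), tree)
            brute = np.abs(p - q).sum() / (p + q).sum()
            assert got == pytest.approx(brute)

    def test_symmetry(self):
        tree = lineage_tree({"a": ("F", "g1"), "b": ("F", "g1"), "c": ("F", "g2")})
        p = {"a": 0.2, "b": 0.3, "c": 0.5}
        q = {"a": 0.6, "b": 0.1, "c": 0.3}
        assert weighted_unifrac(p, q, tree) == pytest.approx(
            weighted_unifrac(q, p, tree))

    def test_missing_taxon_listed(self):
        tree = lineage_tree({"a": ("F",)})
        with pytest.raises(ValueError, match="ghost"):
            weighted_unifrac({"ghost": 1.0}, {"a": 1.0}, tree)

    def test_agrees_with_skbio(self):
        """Cross-check the branch sum against scikit-bio's implementation on
        a non-trivial lineage tree."""
        import skbio.diversity

        lineages = {"a": ("F", "g1"), "b": ("F", "g1"), "c": ("F", "g2"),
                    "d": ("B", "g3")}
        tree = lineage_tree(lineages, with_off_target=False)
        tree.length = 0.0  # skbio wants an explicit root branch length
        taxa = sorted(lineages)
        rng = np.random.default_rng(5)
        p = rng.integers(1, 100, 4)  # skbio takes counts, not fractions
        q = rng.integers(1, 100, 4)
        mine = weighted_unifrac(
            {t: v / p.sum() for t, v in zip(taxa, p)},
            {t: v / q.sum() for t, v in zip(taxa, q)}, tree, normalized=True)
        theirs = skbio.diversity.beta.weighted_unifrac(
            p, q, taxa=taxa, tree=tree, normalized=True)
        assert mine == pytest.approx(float(theirs), abs=1e-12)


class TestRarefaction:
    def test_full_depth_is_100_percent(self):
        counts = [5, 3, 2, 10]
        df = profiler.rarefaction_curve(counts, [20], n_reps=5, seed=1)
        assert df.richness_pct.iloc[0] == 100.0

    def test_monotone_in_expectation(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 50, 40)
        grid = [50, 200, 500, int(counts.sum())]
        df = profiler.rarefaction_curve(counts, grid, n_reps=30, seed=2)
        assert (np.diff(df.mean_richness) >= 0).all()

    def test_singleton_detection_frequency(self):
        # one taxon with exactly 1 read among N: detected with prob d/N
        N, d, reps = 200, 50, 400
        counts = [1] + [199]
        rng_hits = 0
        df_reps = []
        rng = np.random.default_rng(3)
        for _ in range(reps):
            sub = rng.multivariate_hypergeometric(np.array(counts), d)
            rng_hits += sub[0] > 0
        p = d / N
        sd = np.sqrt(reps * p * (1 - p))
        assert abs(rng_hits - reps * p) < 2.58 * sd

    def test_depth_above_total_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            profiler.rarefaction_curve([3, 4], [100], 2, 0)


class TestEnrichment:
    def test_fold_arithmetic(self):
        df = profiler.enrichment_ratio([20, 200], [100, 1000],
                                       [1, 10], [100, 1000])
        assert np.allclose(df.fold, [20.0, 20.0])
        assert df.fold.mean() == pytest.approx(20.0)

    def test_equal_ratios_fold_one(self):
        df = profiler.enrichment_ratio([5], [50], [10], [100])
        assert df.fold.iloc[0] == pytest.approx(1.0)

    def test_zero_control_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            df = profiler.enrichment_ratio([5], [50], [0], [100])
        assert np.isnan(df.fold.iloc[0])


class TestStokes:
    BASE = dict(eta=0.01, Rf=10.0, Ro=5.0, rho_p=1.1, rho_f=1.0)

    def test_equal_densities_error(self):
        with pytest.raises(ValueError, match="sediment"):
            stokes_solve(SedimentationParams(**{**self.BASE, "rho_p": 1.0},
                                             omega=100.0, t=60.0))

    def test_time_scales_inverse_square_of_speed(self):
        t1 = stokes_solve(SedimentationParams(**self.BASE, D=5e-4, omega=100.0))
        t2 = stokes_solve(SedimentationParams(**self.BASE, D=5e-4, omega=200.0))
        assert t1 / t2 == pytest.approx(4.0)

    def test_round_trip(self):
        D0 = 4e-4
        t = stokes_solve(SedimentationParams(**self.BASE, D=D0, omega=150.0))
        D = stokes_solve(SedimentationParams(**self.BASE, omega=150.0, t=t))
        assert D == pytest.approx(D0, abs=1e-9)

    def test_exactly_one_unknown_required(self):
        with pytest.raises(ValueError, match="exactly one"):
            stokes_solve(SedimentationParams(**self.BASE, D=1e-4))
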