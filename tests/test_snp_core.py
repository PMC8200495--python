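"""Filters, density statistic, differential screen, PCA and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutsnp import snp_core as sc
from gutsnp.io_formats import GeneAnnotation, SampleMeta, ValidationError

from conftest import make_site, random_sites
from helpers import (
    oracle_bh,
    oracle_group_coverage,
    oracle_min_support,
    oracle_pseudo_f,
)


class TestMinSupportFilter:
    def test_boundary_five_reads_kept(self):
        site = make_site(s1={"A": 20, "G": 5})
        assert sc.filter_min_support([site], 5).sites == [site]

    def test_four_reads_everywhere_dropped(self):
        site = make_site(s1={"A": 20, "G": 4}, s2={"A": 30, "G": 4})
        assert sc.filter_min_support([site], 5).sites == []

    def test_min_reads_one_keeps_any_variant(self):
        site = make_site(s1={"A": 20, "G": 1})
        assert sc.filter_min_support([site], 1).sites == [site]

    def test_matches_brute_force_on_random_callsets(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            sites = random_sites(rng, 30, [f"s{i}" for i in range(6)])
            for min_reads in (1, 3, 5, 8):
                got = {s.key for s in sc.filter_min_support(sites, min_reads).sites}
                assert got == oracle_min_support(sites, min_reads)


class TestGroupCoverageFilter:
    def _site_observed_in(self, n_obs, n_group, gene="g1"):
        counts = {}
        for i in range(n_group):
            depth = 10 if i < n_obs else 2  # 2 < min_reads=5: unobserved
            counts[f"s{i}"] = {"A": depth - 1, "G": 1}
        return make_site(gene, 1, "A", **counts)

    def test_sixty_percent_boundary_kept(self):
        site = self._site_observed_in(6, 10)
        groups = {f"s{i}": "g" for i in range(10)}
        assert sc.filter_group_coverage([site], groups, 0.6).sites == [site]

    def test_below_sixty_percent_removed(self):
        site = self._site_observed_in(5, 10)
        groups = {f"s{i}": "g" for i in range(10)}
        assert sc.filter_group_coverage([site], groups, 0.6).sites == []

    def test_retained_via_second_group(self):
        # group A: 5/10 observed (0.5); group B: 7/10 observed (0.7)
        counts = {}
        for i in range(10):
            counts[f"a{i}"] = {"A": 10 if i < 5 else 0}
            counts[f"b{i}"] = {"A": 10 if i < 7 else 0}
        site = make_site("g1", 1, "A", **counts)
        groups = {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
        assert sc.filter_group_coverage([site], groups, 0.6).sites == [site]

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            sc.filter_group_coverage([], {}, 0.6)

    def test_matches_brute_force_on_random_callsets(self):
        rng = np.random.default_rng(13)
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
        for _ in range(20):
            sites = random_sites(rng, 30, samples)
            for frac in (0.25, 0.5, 0.75, 1.0):
                got = {
                    s.key
                    for s in sc.filter_group_coverage(sites, groups, frac, 5).sites
                }
                assert got == oracle_group_coverage(sites, groups, frac, 5)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(17)
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
        sites = random_sites(rng, 50, samples)
        sizes_frac = [
            len(sc.filter_group_coverage(sites, groups, f, 5).sites)
            for f in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes_frac == sorted(sizes_frac, reverse=True)
        sizes_reads = [
            len(sc.filter_min_support(sites, r).sites) for r in (1, 3, 5, 10)
        ]
        assert sizes_reads == sorted(sizes_reads, reverse=True)


class TestDensity:
    @pytest.mark.parametrize(
        "n,t,l,expected",
        [(10, 50, 2, 0.1), (0, 50, 2, 0.0), (7, 84.6, 1.5, 7 / (84.6 * 1.5))],
    )
    def test_formula(self, n, t, l, expected):
        assert sc.snp_density(n, t, l) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("t,l", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_domain_errors(self, t, l):
        with pytest.raises(ValidationError):
            sc.snp_density(1, t, l)

    @given(
        n=st.integers(0, 1000),
        t=st.floats(0.1, 500),
        l=st.floats(0.05, 50),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity_in_inverse_t_and_l(self, n, t, l):
        d = sc.snp_density(n, t, l)
        assert sc.snp_density(n, 2 * t, l) == pytest.approx(d / 2, rel=1e-12)
        assert sc.snp_density(n, t, 2 * l) == pytest.approx(d / 2, rel=1e-12)


class TestDensityMatrix:
    def _setup(self):
        annots = {"g1": GeneAnnotation("g1", 500, "sp", "ge")}
        meta = [SampleMeta("s1", "s1", "PWS", 0, 10.0)]
        sites = [
            make_site("g1", p, "A", s1={"A": 5, "G": 8}) for p in (1, 2, 3)
        ]
        return sites, annots, meta

    def test_three_sites_observed(self):
        sites, annots, meta = self._setup()
        m = sc.density_matrix(sites, annots, meta)
        assert m.at["g1", "s1"] == pytest.approx(0.6)  # 3 / (10 * 0.5)

    def test_sample_without_variants_is_zero(self):
        sites, annots, meta = self._setup()
        meta.append(SampleMeta("s2", "s2", "PWS", 0, 10.0))
        m = sc.density_matrix(sites, annots, meta)
        assert (m["s2"] == 0).all()

    def test_site_order_invariance(self):
        sites, annots, meta = self._setup()
        m1 = sc.density_matrix(sites, annots, meta)
        m2 = sc.density_matrix(sites[::-1], annots, meta)
        pd.testing.assert_frame_equal(m1, m2)

    def test_doubling_t_halves_column(self):
        sites, annots, meta = self._setup()
        m1 = sc.density_matrix(sites, annots, meta)
        meta2 = [SampleMeta("s1", "s1", "PWS", 0, 20.0)]
        m2 = sc.density_matrix(sites, annots, meta2)
        assert m2.at["g1", "s1"] == pytest.approx(m1.at["g1", "s1"] / 2)

    def test_unannotated_gene_named_in_error(self):
        sites, _, meta = self._setup()
        with pytest.raises(ValidationError, match="g1"):
            sc.density_matrix(sites, {}, meta)


class TestBhAdjust:
    def test_step_up_closed_form(self):
        pv = [0.01, 0.02, 0.03, 0.04]
        assert sc.bh_adjust(pv) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_matches_oracle_and_never_below_raw(self, pv):
        adj = sc.bh_adjust(pv)
        assert adj == pytest.approx(oracle_bh(pv))
        assert (np.asarray(adj) >= np.asarray(pv) - 1e-12).all()


class TestDifferentialDensity:
    def _matrix(self, rows, samples):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=samples)

    def test_identical_paired_columns_null(self):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = self._matrix([[1, 2, 3, 1, 2, 3], [4, 5, 6, 4, 5, 6]], samples)
        t = sc.differential_density(m, samples[:3], samples[3:], paired=True)
        assert (t["p_value"] == 1.0).all()
        assert not t["significant"].any()

    def test_fold_change_boundary_is_strict(self):
        samples = ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"]
        m = self._matrix([[0.8] * 4 + [0.1] * 4], samples)
        t = sc.differential_density(m, samples[:4], samples[4:], paired=True)
        # pseudocount is half the minimum nonzero density (0.05):
        # fc = 0.85/0.15 > 8 would be wrong; with means 0.8/0.1 it is
        fc = t["fold_change"].iloc[0]
        assert t["direction"].iloc[0] == "higher-pre"
        assert fc == pytest.approx((0.8 + 0.05) / (0.1 + 0.05))
        assert not t["significant_fc"].iloc[0] or fc > 8

    def test_swap_groups_flips_direction_keeps_p(self):
        rng = np.random.default_rng(5)
        samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        m = self._matrix(rng.gamma(2, 1, size=(8, 12)), samples)
        t1 = sc.differential_density(m, samples[:6], samples[6:], paired=True)
        t2 = sc.differential_density(m, samples[6:], samples[:6], paired=True)
        assert t1["p_value"].values == pytest.approx(t2["p_value"].values)
        flipped = t2["direction"].map(
            {"higher-pre": "higher-post", "higher-post": "higher-pre"}
        )
        assert (t1["direction"] == flipped).all()

    def test_all_zero_gene_excluded(self):
        samples = ["a1", "a2", "b1", "b2"]
        m = self._matrix([[0, 0, 0, 0], [1, 2, 3, 4]], samples)
        t = sc.differential_density(m, samples[:2], samples[2:], paired=True)
        assert list(t.index) == ["g1"]

    def test_small_group_rejected(self):
        m = self._matrix([[1, 2]], ["a1", "b1"])
        with pytest.raises(ValidationError):
            sc.differential_density(m, ["a1"], ["b1"], paired=True)


class TestPca:
    def test_identical_samples_score_zero(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["g1", "g2"])
        scores, _ = sc.pca_scores(m)
        assert np.allclose(scores.values, 0)

    def test_collinear_samples_explained_by_pc1(self):
        base = np.array([1.0, 2.0, 3.0])
        m = pd.DataFrame(
            {f"s{i}": base * i for i in range(1, 5)}, index=["g1", "g2", "g3"]
        )
        _, evr = sc.pca_scores(m)
        assert evr[0] == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        m = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError):
            sc.pca_scores(m)


class TestPermanova:
    def _random_dist(self, rng, n):
        x = rng.normal(size=(n, 4))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(x))

    def test_equal_distances_give_p_one(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        labels = ["A"] * 4 + ["B"] * 4
        res = sc.permanova(d, labels, n_perm=99, seed=0)
        assert res["p_value"] == 1.0

    def test_singleton_group_rejected(self):
        d = self._random_dist(np.random.default_rng(0), 5)
        with pytest.raises(ValidationError):
            sc.permanova(d, ["A"] * 4 + ["B"], n_perm=9, seed=0)

    def test_seeded_reproducibility(self):
        d = self._random_dist(np.random.default_rng(1), 10)
        labels = ["A"] * 5 + ["B"] * 5
        r1 = sc.permanova(d, labels, n_perm=199, seed=42)
        r2 = sc.permanova(d, labels, n_perm=199, seed=42)
        assert r1 == r2
        assert 0 < r1["p_value"] <= 1

    def test_pseudo_f_matches_plain_loop_oracle(self):
        rng = np.random.default_rng(2)
        d = self._random_dist(rng, 9)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = sc.permanova(d, labels, n_perm=9, seed=0)
        assert res["pseudo_F"] == pytest.approx(oracle_pseudo_f(d, labels))

    def test_pseudo_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        d = self._random_dist(rng, 12)
        labels = ["A"] * 6 + ["B"] * 6
        res = sc.permanova(d, labels, n_perm=9, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d), grouping=labels, permutations=9
        )
        assert res["pseudo_F"] == pytest.approx(float(ref["test statistic"]))
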