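import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha

import rhizocomm as rc
from rhizocomm.diversity import OrdinationResult, alpha_anova


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], np.log(4)),
            ([10], 0.0),
            ([70, 20, 10], -(0.7 * np.log(0.7) + 0.2 * np.log(0.2) + 0.1 * np.log(0.1))),
        ],
    )
    def test_known_values(self, counts, expected):
        assert rc.shannon(counts) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            rc.shannon([0, 0])

    def test_matches_skbio_natural_log(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 50, size=30)
            if v.sum() == 0:
                continue
            assert rc.shannon(v) == pytest.approx(
                float(skbio_alpha.shannon(v, base=np.e)), abs=1e-9
            )

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_order_invariant_and_uniform_maximal(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(1, 100, size=8)
        assert rc.shannon(v) == pytest.approx(
            rc.shannon(rng.permutation(v)), abs=1e-12
        )
        # uniform composition is the strict maximum for fixed richness
        assert rc.shannon(v) <= np.log(v.size) + 1e-12


class TestSimpson:
    def test_monoculture_is_one(self):
        assert rc.simpson([7]) == 1.0

    def test_two_singletons_zero(self):
        assert rc.simpson([1, 1]) == 0.0

    def test_direct_formula(self):
        # (70*69 + 20*19 + 10*9) / (100*99)
        assert rc.simpson([70, 20, 10]) == pytest.approx(5300 / 9900, abs=1e-12)

    def test_anticorrelated_with_diversity(self):
        assert rc.simpson([50, 50]) < rc.simpson([99, 1])

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            rc.simpson([1])


class TestChao1:
    def test_no_singletons_returns_observed(self):
        assert rc.chao1([5, 3, 2, 2]) == 4.0

    def test_direct_formula(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 6, 7, 8]
        assert rc.chao1(counts) == pytest.approx(12.0)

    def test_adding_individuals_removes_singleton_boost(self):
        counts = np.array([1, 1, 1, 1, 2, 2, 5, 6, 7, 8])
        assert rc.chao1(counts + 1) == 10.0

    def test_matches_skbio_bias_corrected(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.integers(0, 10, size=40)
            if v.sum() == 0:
                continue
            assert rc.chao1(v) == pytest.approx(
                float(skbio_alpha.chao1(v, bias_corrected=True)), abs=1e-9
            )

    def test_rejects_non_integer(self):
        with pytest.raises(ValueError):
            rc.chao1([1.5, 2.0])


class TestAce:
    def test_no_rare_class_returns_observed(self):
        assert rc.ace([11, 20, 30]) == 3.0

    def test_hand_evaluated_fixture(self):
        # F1=3, F2=2, F3=1 (rare), plus 5 abundant taxa (>10)
        counts = [1, 1, 1, 2, 2, 3, 11, 12, 13, 14, 15]
        s_rare, s_abund, n_rare, f1 = 6, 5, 10, 3
        c_ace = 1 - f1 / n_rare
        sum_term = 1 * 0 * 3 + 2 * 1 * 2 + 3 * 2 * 1  # sum i(i-1)F_i
        gamma2 = max(0.0, (s_rare / c_ace) * sum_term / (n_rare * 9) - 1)
        expected = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
        assert rc.ace(counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.integers(1, 30, size=25)
            f1 = (v == 1).sum()
            n_rare = v[v <= 10].sum()
            if n_rare in (0, 1) or f1 == n_rare:
                continue
            assert rc.ace(v) == pytest.approx(float(skbio_alpha.ace(v)), rel=1e-9)

    def test_estimate_at_least_observed_with_singletons(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = np.concatenate([[1], rng.integers(1, 20, size=15)])
            s_obs = (v > 0).sum()
            assert rc.ace(v) >= s_obs - 1e-9

    def test_all_singletons_falls_back_to_chao1(self):
        with pytest.warns(UserWarning, match="Chao1"):
            out = rc.ace([1, 1, 1])
        assert out == rc.chao1([1, 1, 1])


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        df = pd.DataFrame({"a": [3, 1], "b": [3, 1]}, index=["t1", "t2"])
        d = rc.bray_curtis(rc.CommunityMatrix(df))
        assert d["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame({"a": [3, 0], "b": [0, 5]}, index=["t1", "t2"])
        d = rc.bray_curtis(rc.CommunityMatrix(df))
        assert d["a", "b"] == 1.0

    def test_direct_formula(self):
        df = pd.DataFrame({"a": [3, 1, 0], "b": [1, 1, 2]},
                          index=["t1", "t2", "t3"])
        d = rc.bray_curtis(rc.CommunityMatrix(df))
        assert d["a", "b"] == pytest.approx(0.5)

    def test_bounded_symmetric_zero_diagonal(self, small_dataset):
        d = np.asarray(rc.bray_curtis(small_dataset.matrix).data)
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T, atol=1e-15)
        assert np.diagonal(d).max() == 0.0

    def test_all_zero_sample_errors(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["t1", "t2"])
        with pytest.raises(ValueError, match="b"):
            rc.bray_curtis(rc.CommunityMatrix(df))


class TestPcoa:
    def test_collinear_points_single_positive_axis(self):
        pts = np.array([0.0, 1.0, 4.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]),
                           ids=["a", "b", "c"])
        res = rc.pcoa(d)
        assert res.n_axes == 1
        coords = res.coordinates.to_numpy().ravel()
        recon = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(recon, np.asarray(d.data), atol=1e-8)

    def test_axis_variance_sorted_descending(self, small_dataset):
        res = rc.pcoa(rc.bray_curtis(small_dataset.matrix))
        assert (np.diff(res.proportion_explained) <= 1e-12).all()
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[str(i) for i in range(12)])
        res = rc.pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, np.asarray(d.data), atol=1e-6)

    def test_matches_skbio_eigenvalues(self, small_dataset):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        d = rc.bray_curtis(small_dataset.matrix)
        ours = rc.pcoa(d)
        theirs = skbio_pcoa(d, number_of_dimensions=5)
        np.testing.assert_allclose(
            ours.eigenvalues[:5], theirs.eigvals.to_numpy()[:5], atol=1e-8
        )


class TestPermanova:
    def _meta(self, labels):
        rows = [
            {"sample_id": f"S{i}", "compartment": lab, "stage": "tillering",
             "replicate": i}
            for i, lab in enumerate(labels)
        ]
        return rc.SampleMetadata(pd.DataFrame(rows))

    def test_saturated_separation_minimal_p(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.01, (9, 2)),
                         rng.normal(50, 0.01, (9, 2))])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"S{i}" for i in range(18)])
        meta = self._meta(["bulk"] * 9 + ["rhizoplane"] * 9)
        res = rc.permanova(d, meta, "compartment", n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r_squared > 0.99

    def test_two_point_clusters_r2_is_one(self):
        mat = np.zeros((6, 6))
        mat[:3, 3:] = 1.0
        mat[3:, :3] = 1.0
        d = DistanceMatrix(mat, ids=[f"S{i}" for i in range(6)])
        meta = self._meta(["bulk"] * 3 + ["rhizoplane"] * 3)
        res = rc.permanova(d, meta, "compartment", n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_pseudo_f_matches_skbio(self, small_dataset):
        from skbio.stats.distance import permanova as skbio_permanova

        d = rc.bray_curtis(small_dataset.matrix)
        meta = small_dataset.metadata
        ours = rc.permanova(d, meta, "compartment", n_perm=99, seed=1)
        grouping = meta.factor("compartment").reindex(list(d.ids)).to_numpy()
        theirs = skbio_permanova(d, grouping, permutations=99)
        assert ours.pseudo_f == pytest.approx(
            float(theirs["test statistic"]), rel=1e-9
        )

    def test_p_value_lower_bound(self):
        # p can never undercut 1/(n_perm + 1) by construction
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"S{i}" for i in range(8)])
        meta = self._meta(["bulk"] * 4 + ["rhizoplane"] * 4)
        res = rc.permanova(d, meta, "compartment", n_perm=49, seed=2)
        assert res.p_value >= 1 / 50

    def test_degenerate_factor_errors(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=["S0", "S1", "S2"])
        meta = self._meta(["bulk", "bulk", "rhizoplane"])
        with pytest.raises(ValueError):
            rc.permanova(d, meta, "compartment")


class TestGroupCompare:
    def test_identical_groups_share_letter(self, design_metadata):
        values = pd.Series(1.0, index=design_metadata.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            out = rc.group_compare(values, design_metadata, "compartment")
        letters = out[None].letters
        assert set(letters.values()) == {"a"}

    def test_separated_group_gets_own_letter(self, design_metadata):
        # compartment means 100, 100, 200 with sd ~1: the third compartment
        # must be lettered apart from the first two
        rng = np.random.default_rng(7)
        meta = design_metadata
        base = {"bulk": 100.0, "rhizosphere": 100.0, "rhizoplane": 200.0}
        values = pd.Series(
            {
                row.sample_id: base[row.compartment] + rng.normal(0, 1)
                for row in meta.table.itertuples()
            }
        )
        out = rc.group_compare(values, meta, "compartment")[None]
        letters = out.letters
        assert letters["bulk"] == letters["rhizosphere"]
        assert letters["rhizoplane"] != letters["bulk"]

    def test_bonferroni_is_capped_multiplication(self, design_metadata):
        rng = np.random.default_rng(8)
        values = pd.Series(
            rng.normal(size=27), index=design_metadata.sample_ids
        )
        out = rc.group_compare(values, design_metadata, "compartment")[None]
        mw = out.mannwhitney
        assert len(mw) == 3
        for _, row in mw.iterrows():
            assert row["p_bonf"] == pytest.approx(min(1.0, row["p_raw"] * 3))

    def test_stratified_by_stage(self, design_metadata):
        rng = np.random.default_rng(9)
        values = pd.Series(
            rng.normal(size=27), index=design_metadata.sample_ids
        )
        out = rc.group_compare(
            values, design_metadata, "compartment", stratify_by="stage"
        )
        assert set(out) == {"tillering", "heading", "mature"}


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (6.96, 6.43, 8.24),
            (3729.68, 3244.54, 14.95),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert rc.percent_increase(a, b) == expected

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            rc.percent_increase(1.0, 0.0)


def test_alpha_table_and_two_way_anova(small_dataset):
    alpha = rc.alpha_diversity_table(small_dataset.matrix)
    assert set(alpha.columns) == {"observed", "shannon", "simpson", "chao1", "ace"}
    assert (alpha["chao1"] >= alpha["observed"] - 1e-9).all()
    table = alpha_anova(alpha["shannon"], small_dataset.metadata)
    assert "C(compartment)" in table.index
    assert "C(compartment):C(stage)" in table.index
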