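import numpy as np
import pandas as pd
import pytest

import rhizocomm as rc
from rhizocomm.assembly import (
    AssemblyResult,
    PROCESS_LABELS,
    _bray_curtis_pair,
)
from rhizocomm.simulate import neutral_regime_config, selection_regime_config
from rhizocomm.tree import patristic_distances


def brute_force_beta_mntd(m, tree, pair):
    """Independent double-loop oracle over the full patristic matrix."""
    d = patristic_distances(tree)
    j, k = pair
    taxa_j = [x for x in m.taxon_ids if m.data.loc[x, j] > 0]
    taxa_k = [x for x in m.taxon_ids if m.data.loc[x, k] > 0]
    fj = np.array([m.data.loc[x, j] for x in taxa_j], float)
    fk = np.array([m.data.loc[x, k] for x in taxa_k], float)
    fj, fk = fj / fj.sum(), fk / fk.sum()
    total = 0.0
    for w, x in zip(fj, taxa_j):
        total += w * min(d[x, y] for y in taxa_k)
    for w, y in zip(fk, taxa_k):
        total += w * min(d[x, y] for x in taxa_j)
    return total / 2.0


class TestBetaMntd:
    def test_identical_communities_zero(self):
        t = rc.PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        df = pd.DataFrame({"s1": [3, 2, 1], "s2": [3, 2, 1]},
                          index=["A", "B", "C"])
        m = rc.CommunityMatrix(df)
        assert rc.beta_mntd(m, t, ("s1", "s2")) == 0.0

    def test_two_singleton_communities(self):
        t = rc.PhyloTree.from_newick("(A:2,B:2);")
        df = pd.DataFrame({"s1": [5, 0], "s2": [0, 9]}, index=["A", "B"])
        m = rc.CommunityMatrix(df)
        assert rc.beta_mntd(m, t, ("s1", "s2")) == pytest.approx(4.0)

    def test_matches_brute_force_on_random_pairs(self):
        for seed in range(5):
            tree = rc.simulate_tree(30, seed=seed)
            rng = np.random.default_rng(seed)
            data = rng.integers(0, 20, size=(30, 2))
            data[0] += 1  # keep both samples nonempty
            m = rc.CommunityMatrix(
                pd.DataFrame(data, index=tree.tip_labels, columns=["x", "y"])
            )
            assert rc.beta_mntd(m, tree, ("x", "y")) == pytest.approx(
                brute_force_beta_mntd(m, tree, ("x", "y")), abs=1e-9
            )

    def test_missing_tip_named(self):
        t = rc.PhyloTree.from_newick("(A:1,B:1);")
        df = pd.DataFrame({"s1": [1, 1], "s2": [1, 1]}, index=["A", "Zed"])
        with pytest.raises(ValueError, match="Zed"):
            rc.beta_mntd(rc.CommunityMatrix(df), t, ("s1", "s2"))

    def test_nonnegative(self, small_dataset):
        m, t = small_dataset.matrix, small_dataset.tree
        ids = m.sample_ids
        for pair in [(ids[0], ids[5]), (ids[3], ids[20])]:
            assert rc.beta_mntd(m, t, pair) >= 0


class TestBetaNti:
    def test_identical_communities_have_degenerate_null(self):
        # shared taxa stay shared under any tip shuffle, so identical
        # communities give sd_null = 0 and a missing betaNTI
        t = rc.simulate_tree(10, seed=0)
        df = pd.DataFrame(
            {"s1": np.arange(1, 11), "s2": np.arange(1, 11)},
            index=t.tip_labels,
        )
        m = rc.CommunityMatrix(df)
        with pytest.warns(UserWarning, match="degenerate null"):
            out = rc.beta_nti(m, t, n_null=49, seed=0)
        assert np.isnan(out["bnti"]).all()

    def test_opposite_deep_clades_give_positive_bnti(self):
        # two communities confined to opposite clades of a two-clade tree
        # are phylogenetically overdispersed relative to the shuffle null
        hits = 0
        for seed in range(20):
            left = ",".join(f"L{i}:0.1" for i in range(8))
            right = ",".join(f"R{i}:0.1" for i in range(8))
            t = rc.PhyloTree.from_newick(f"(({left}):5,({right}):5);")
            rng = np.random.default_rng(seed)
            s1 = np.concatenate([rng.integers(1, 20, 8), np.zeros(8, int)])
            s2 = np.concatenate([np.zeros(8, int), rng.integers(1, 20, 8)])
            m = rc.CommunityMatrix(
                pd.DataFrame({"s1": s1, "s2": s2},
                             index=[f"L{i}" for i in range(8)]
                             + [f"R{i}" for i in range(8)])
            )
            out = rc.beta_nti(m, t, n_null=199, seed=seed)
            hits += out["bnti"].iloc[0] >= 2
        assert hits >= 19

    def test_invariant_to_taxon_row_order(self, small_dataset):
        m, t = small_dataset.matrix, small_dataset.tree
        pair = [(m.sample_ids[0], m.sample_ids[9])]
        a = rc.beta_nti(m, t, n_null=99, seed=3, pairs=pair)
        shuffled = rc.CommunityMatrix(
            m.data.sample(frac=1, random_state=1), m.semantics
        )
        b = rc.beta_nti(shuffled, t, n_null=99, seed=3, pairs=pair)
        assert a["bnti"].iloc[0] == pytest.approx(b["bnti"].iloc[0], abs=1e-12)

    def test_invariant_to_branch_length_scaling(self, small_dataset):
        # betaNTI is a z-score, so uniform branch scaling cancels
        m, t = small_dataset.matrix, small_dataset.tree
        pair = [(m.sample_ids[2], m.sample_ids[22])]
        a = rc.beta_nti(m, t, n_null=99, seed=4, pairs=pair)
        scaled = rc.PhyloTree.from_newick(t.to_newick())
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 10.0
        b = rc.beta_nti(m, scaled, n_null=99, seed=4, pairs=pair)
        assert a["bnti"].iloc[0] == pytest.approx(b["bnti"].iloc[0], abs=1e-9)

    def test_missing_taxa_error_and_prune(self, small_dataset):
        m, t = small_dataset.matrix, small_dataset.tree
        extra = m.data.copy()
        extra.loc["ghost"] = 1
        bad = rc.CommunityMatrix(extra)
        with pytest.raises(ValueError, match="ghost"):
            rc.beta_nti(bad, t, n_null=9, seed=0, pairs=[(m.sample_ids[0], m.sample_ids[1])])
        with pytest.warns(UserWarning, match="pruning"):
            out = rc.beta_nti(
                bad, t, n_null=9, seed=0,
                pairs=[(m.sample_ids[0], m.sample_ids[1])],
                missing_taxa="prune",
            )
        assert len(out) == 1


class TestRcBray:
    @staticmethod
    def independent_rc(m, pair, n_null, seed):
        """From-scratch rank-counting reimplementation sharing only the
        documented RNG draw order (choice of taxa, then multinomial fill)."""
        counts = np.round(m.counts()).astype(int)
        idx = {s: i for i, s in enumerate(m.sample_ids)}
        xj = counts[:, idx[pair[0]]]
        xk = counts[:, idx[pair[1]]]
        occ = (counts > 0).sum(axis=1) / (counts > 0).sum()
        pool = counts.sum(axis=1)
        obs = _bray_curtis_pair(xj.astype(float), xk.astype(float))
        rng = np.random.default_rng(seed)
        below = ties = 0
        for _ in range(n_null):
            nulls = []
            for template in (xj, xk):
                rich, tot = int((template > 0).sum()), int(template.sum())
                chosen = rng.choice(len(pool), size=rich, replace=False, p=occ)
                vec = np.zeros(len(pool))
                vec[chosen] = 1
                if tot > rich:
                    pfill = pool[chosen] / pool[chosen].sum()
                    vec[chosen] += rng.multinomial(tot - rich, pfill)
                nulls.append(vec)
            bc = _bray_curtis_pair(*nulls)
            below += bc < obs
            ties += bc == obs
        return ((below + 0.5 * ties) / n_null - 0.5) * 2

    def test_matches_independent_reimplementation(self):
        df = pd.DataFrame(
            {"s1": [5, 0, 3, 1], "s2": [1, 4, 0, 2], "s3": [2, 2, 2, 2]},
            index=["a", "b", "c", "d"],
        )
        m = rc.CommunityMatrix(df)
        for pair in [("s1", "s2"), ("s1", "s3")]:
            assert rc.rc_bray(m, pair, n_null=99, seed=7) == pytest.approx(
                self.independent_rc(m, pair, 99, 7)
            )

    def test_extreme_ranks_hit_plus_minus_one(self):
        # identical, perfectly even samples are far more similar than any
        # plausible null draw -> RC = -1; two maximally uneven, disjoint
        # samples in a diverse pool -> RC = +1
        rng = np.random.default_rng(0)
        even = pd.DataFrame(
            {"s1": [50] * 10, "s2": [50] * 10,
             **{f"r{i}": rng.integers(1, 100, 10) for i in range(4)}},
            index=[f"t{i}" for i in range(10)],
        )
        m = rc.CommunityMatrix(even)
        assert rc.rc_bray(m, ("s1", "s2"), n_null=99, seed=1) == -1.0

    def test_bounded(self, small_dataset):
        m = small_dataset.matrix
        v = rc.rc_bray(m, (m.sample_ids[0], m.sample_ids[10]), n_null=49, seed=2)
        assert -1.0 <= v <= 1.0


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti,rcv,expected",
        [
            (-3.1, 0.2, "homogeneous selection"),
            (0.0, 0.99, "dispersal limitation"),
            (1.9, 0.0, "undominated"),
            (2.5, -1.0, "heterogeneous selection"),
            (-2.0, 0.99, "dispersal limitation"),  # boundary is stochastic
            (2.0, -0.99, "homogenizing dispersal"),
            (0.0, 0.95, "undominated"),  # RC boundary is strict
            (0.0, -0.95, "undominated"),
            (float("nan"), 0.5, "unclassified"),
        ],
    )
    def test_threshold_table(self, bnti, rcv, expected):
        assert rc.classify_process(bnti, rcv) == expected

    def test_exhaustive_partition(self):
        # every finite (betaNTI, RC) combination receives exactly one of
        # the five labels
        for b in np.linspace(-4, 4, 41):
            for r in np.linspace(-1, 1, 41):
                assert rc.classify_process(b, r) in PROCESS_LABELS


class TestProcessSummary:
    def _result(self, labels, bntis, meta):
        ids = meta.sample_ids
        rows = []
        i = 0
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                rows.append(
                    {
                        "sample_i": ids[a],
                        "sample_j": ids[b],
                        "beta_mntd": 1.0,
                        "null_mean": 1.0,
                        "null_sd": 1.0,
                        "bnti": bntis[i % len(bntis)],
                        "rc_bray": 0.0,
                        "process": labels[i % len(labels)],
                    }
                )
                i += 1
        return AssemblyResult(pd.DataFrame(rows))

    def test_all_selection_gives_full_deterministic_fraction(self, design_metadata):
        res = self._result(["heterogeneous selection"], [3.0], design_metadata)
        summary = rc.process_summary(res, design_metadata)
        assert (summary["deterministic_fraction"] == 100.0).all()
        assert (summary["heterogeneous selection"] == 100.0).all()

    def test_half_and_half(self, design_metadata):
        res = self._result(
            ["heterogeneous selection", "undominated"], [3.0, 0.0],
            design_metadata,
        )
        summary = rc.process_summary(res, design_metadata)
        assert summary["deterministic_fraction"].iloc[0] == pytest.approx(50.0)

    def test_percentages_sum_to_hundred(self, small_dataset):
        result = rc.assembly_analysis(
            small_dataset.matrix, small_dataset.tree, n_null=49, seed=0
        )
        summary = rc.process_summary(result, small_dataset.metadata)
        totals = summary[list(PROCESS_LABELS)].sum(axis=1)
        np.testing.assert_allclose(totals, 100.0, atol=1e-9)


class TestRegimeRecovery:
    def test_selection_vs_neutral_quick(self):
        # a compressed version of the full 50-seed recovery study: the
        # selection regime must look deterministic between environments,
        # the neutral regime stochastic
        sel_ok = neu_ok = 0
        n_rep = 5
        for seed in range(n_rep):
            ds = rc.simulate_dataset(selection_regime_config(seed))
            comp = ds.metadata.factor("compartment")
            between = [
                (a, b)
                for i, a in enumerate(ds.matrix.sample_ids)
                for b in ds.matrix.sample_ids[i + 1 :]
                if comp[a] != comp[b]
            ]
            res = rc.assembly_analysis(
                ds.matrix, ds.tree, n_null=99, seed=seed, pairs=between
            )
            sel_ok += (
                res.deterministic_fraction() > 80
                and res.pairs["process"].value_counts().idxmax()
                == "heterogeneous selection"
            )
            ds = rc.simulate_dataset(neutral_regime_config(seed))
            res = rc.assembly_analysis(ds.matrix, ds.tree, n_null=99, seed=seed)
            neu_ok += res.deterministic_fraction() < 20
        assert sel_ok >= n_rep - 1
        assert neu_ok >= n_rep - 1
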