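"""Validation studies: oracle equivalence, calibration and recovery rates.

These are the statistical checks a user can run to convince themselves the
estimators behave as designed: the vectorized betaMNTD against a naive
double loop, null-model regime recovery on generated data with known
assembly regimes, planted-block recovery in the co-occurrence stage,
PERMANOVA type-I error calibration, and beta-regression slope recovery.
Each study returns plain dictionaries of summary numbers.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special

import rhizocomm as rc
from rhizocomm.simulate import neutral_regime_config, selection_regime_config
from rhizocomm.tree import patristic_distances


def beta_mntd_oracle_error(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |vectorized - double-loop| betaMNTD over random (tree, pair)s."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        tree = rc.simulate_tree(30, seed=int(rng.integers(2**31)))
        data = rng.integers(0, 20, size=(30, 2))
        data[rng.integers(30), 0] += 1
        data[rng.integers(30), 1] += 1
        m = rc.CommunityMatrix(
            pd.DataFrame(data, index=tree.tip_labels, columns=["x", "y"])
        )
        fast = rc.beta_mntd(m, tree, ("x", "y"))
        d = patristic_distances(tree)
        taxa_j = [t for t in m.taxon_ids if m.data.loc[t, "x"] > 0]
        taxa_k = [t for t in m.taxon_ids if m.data.loc[t, "y"] > 0]
        fj = np.array([m.data.loc[t, "x"] for t in taxa_j], float)
        fk = np.array([m.data.loc[t, "y"] for t in taxa_k], float)
        fj, fk = fj / fj.sum(), fk / fk.sum()
        slow = 0.5 * (
            sum(w * min(d[a, b] for b in taxa_k) for w, a in zip(fj, taxa_j))
            + sum(w * min(d[a, b] for a in taxa_j) for w, b in zip(fk, taxa_k))
        )
        worst = max(worst, abs(fast - slow))
    return {"max_abs_error": worst, "n": n_instances}


def regime_recovery_study(
    n_rep: int = 50, n_null: int = 199, seed: int = 0
) -> dict:
    """Recover the planted assembly regime from generated datasets.

    Selection datasets (two distant environment optima, narrow filtering)
    are scored on between-environment pairs: success means a deterministic
    fraction above 80% with "heterogeneous selection" as the modal label.
    Neutral datasets succeed when the deterministic fraction stays below
    20% over all pairs.
    """
    rng = np.random.default_rng(seed)
    sel_ok = neu_ok = 0
    sel_det, neu_det = [], []
    for _ in range(n_rep):
        rep_seed = int(rng.integers(2**31))
        ds = rc.simulate_dataset(selection_regime_config(rep_seed))
        comp = ds.metadata.factor("compartment")
        between = [
            (a, b)
            for a, b in combinations(ds.matrix.sample_ids, 2)
            if comp[a] != comp[b]
        ]
        res = rc.assembly_analysis(
            ds.matrix, ds.tree, n_null=n_null, seed=rep_seed, pairs=between
        )
        det = res.deterministic_fraction()
        sel_det.append(det)
        modal = res.pairs["process"].value_counts().idxmax()
        sel_ok += det > 80 and modal == "heterogeneous selection"

        ds = rc.simulate_dataset(neutral_regime_config(rep_seed))
        res = rc.assembly_analysis(
            ds.matrix, ds.tree, n_null=n_null, seed=rep_seed
        )
        det = res.deterministic_fraction()
        neu_det.append(det)
        neu_ok += det < 20
    return {
        "selection_success_rate": sel_ok / n_rep,
        "neutral_success_rate": neu_ok / n_rep,
        "selection_deterministic_fraction_mean": float(np.mean(sel_det)),
        "neutral_deterministic_fraction_mean": float(np.mean(neu_det)),
        "n": n_rep,
    }


def network_recovery_study(n_rep: int = 50, seed: int = 0) -> dict:
    """Planted-block edge sensitivity and noise false-edge rate at 27
    samples, neutral background."""
    rng = np.random.default_rng(seed)
    sens, fp = [], []
    for _ in range(n_rep):
        cfg = rc.SimulationConfig(
            n_taxa=60,
            depth=10_000,
            seed=int(rng.integers(2**31)),
            n_blocks=1,
            block_size=6,
            sigma_env={"bulk": 1e9, "rhizosphere": 1e9, "rhizoplane": 1e9},
        )
        ds = rc.simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = rc.build_network(ds.matrix, prevalence=0.5)
        block = set(ds.truth.blocks[0]["taxa"])
        pairs = list(combinations(sorted(block), 2))
        sens.append(
            sum(g.graph.has_edge(a, b) for a, b in pairs) / len(pairs)
        )
        noise_edges = sum(
            1 for u, v in g.graph.edges if not (u in block and v in block)
        )
        n_noise_pairs = 60 * 59 // 2 - len(pairs)
        fp.append(noise_edges / n_noise_pairs)
    return {
        "sensitivity": float(np.mean(sens)),
        "false_edge_rate": float(np.mean(fp)),
        "n": n_rep,
    }


def permanova_type_i_study(
    n_sim: int = 1000,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    n_per_group: int = 6,
) -> dict:
    """Rejection rate when group labels carry no signal.

    Each simulation draws i.i.d. bivariate normal samples for three
    arbitrary groups, computes Euclidean distances and runs the seeded
    PERMANOVA; under the null the rejection rate at ``alpha`` should match
    ``alpha``.
    """
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    labels = (
        ["bulk"] * n_per_group
        + ["rhizosphere"] * n_per_group
        + ["rhizoplane"] * n_per_group
    )
    n = len(labels)
    meta = rc.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "compartment": labels,
                "stage": "tillering",
                "replicate": list(range(n)),
            }
        )
    )
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_sim):
        pts = rng.normal(size=(n, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"S{i}" for i in range(n)])
        res = rc.permanova(
            d, meta, "compartment", n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rejections += res.p_value <= alpha
    return {"rejection_rate": rejections / n_sim, "n": n_sim}


def beta_regression_recovery_study(
    n_rep: int = 200,
    slope: float = 1.0,
    intercept: float = -2.0,
    phi: float = 50.0,
    seed: int = 0,
) -> dict:
    """Slope recovery and Wald 95% CI coverage at the 27-sample design."""
    rng = np.random.default_rng(seed)
    x = np.repeat([0.0, 1.0, 2.0], 9)
    slopes, covered = [], 0
    for _ in range(n_rep):
        mu = special.expit(intercept + slope * x)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        fit = rc.beta_regression_fit(y, x)
        slopes.append(fit.slope)
        lo = fit.slope - 1.96 * fit.stderr
        hi = fit.slope + 1.96 * fit.stderr
        covered += lo <= slope <= hi
    return {
        "mean_slope": float(np.mean(slopes)),
        "coverage": covered / n_rep,
        "n": n_rep,
    }


def process_grid_agreement(n_grid: int = 41) -> dict:
    """Agreement of classify_process with a direct statement of the
    five-way threshold table over a grid straddling every boundary."""

    def expected(bnti, rcv):
        if bnti < -2:
            return "homogeneous selection"
        if bnti > 2:
            return "heterogeneous selection"
        if rcv > 0.95:
            return "dispersal limitation"
        if rcv < -0.95:
            return "homogenizing dispersal"
        return "undominated"

    bnti_grid = np.concatenate(
        [np.linspace(-4, 4, n_grid), [-2.0, -2.001, -1.999, 2.0, 2.001, 1.999]]
    )
    rc_grid = np.concatenate(
        [np.linspace(-1, 1, n_grid), [-0.95, -0.951, -0.949, 0.95, 0.951, 0.949]]
    )
    total = agree = 0
    for b in bnti_grid:
        for r in rc_grid:
            total += 1
            agree += rc.classify_process(b, r) == expected(b, r)
    return {"agreement": agree / total, "n": total}
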