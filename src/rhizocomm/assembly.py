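"""Null-model partitioning of community assembly processes.

Two pairwise null models are combined:

* betaMNTD / betaNTI — phylogenetic turnover.  betaMNTD is the
  abundance-weighted mean distance from each taxon to its nearest relative
  in the other community; betaNTI is its z-score against a null that
  shuffles which tips the taxa occupy.  |betaNTI| > 2 indicates
  deterministic assembly (selection): betaNTI < -2 homogeneous selection,
  betaNTI > +2 heterogeneous selection.
* RC_Bray — taxonomic turnover.  Null communities preserve each sample's
  richness and total abundance while drawing taxa by regional occurrence
  frequency and filling individuals by regional relative abundance; the
  observed Bray-Curtis is ranked against the nulls and rescaled to [-1, 1].

Pairs not dominated by selection are classified by RC_Bray: > 0.95
dispersal limitation, < -0.95 homogenizing dispersal, otherwise
undominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from rhizocomm.matrix import CommunityMatrix, SampleMetadata
from rhizocomm.tree import PhyloTree, patristic_distances

PROCESS_LABELS = (
    "homogeneous selection",
    "heterogeneous selection",
    "dispersal limitation",
    "homogenizing dispersal",
    "undominated",
)


@dataclass
class AssemblyResult:
    """Pairwise null-model statistics and per-pair process labels."""

    pairs: pd.DataFrame  # sample_i, sample_j, beta_mntd, null_mean,
    # null_sd, bnti, rc_bray, process

    def deterministic_fraction(self) -> float:
        """% of pairs with |betaNTI| > 2, over pairs with defined betaNTI."""
        bnti = self.pairs["bnti"].dropna()
        if bnti.empty:
            return float("nan")
        return float(100.0 * (bnti.abs() > 2).mean())


def _check_tree_coverage(
    m: CommunityMatrix, t: PhyloTree, missing_taxa: str
) -> CommunityMatrix:
    tips = set(t.tip_labels)
    absent = [x for x in m.taxon_ids if x not in tips]
    if not absent:
        return m
    if missing_taxa == "error":
        raise ValueError(
            f"{len(absent)} matrix taxa are not on the tree "
            f"(e.g. {absent[:5]}); pass missing_taxa='prune' to drop them"
        )
    if missing_taxa == "prune":
        warnings.warn(
            f"pruning {len(absent)} matrix taxa absent from the tree",
            stacklevel=3,
        )
        return CommunityMatrix(m.data.drop(index=absent), m.semantics)
    raise ValueError("missing_taxa must be 'error' or 'prune'")


def _beta_mntd_core(
    d_union: np.ndarray,
    pos_j: np.ndarray,
    pos_k: np.ndarray,
    w_j: np.ndarray,
    w_k: np.ndarray,
) -> float:
    """Abundance-weighted betaMNTD on a union-indexed patristic matrix.

    ``pos_j``/``pos_k`` index the taxa present in each sample within the
    union; ``w_j``/``w_k`` are their relative abundances (summing to 1).
    A taxon present in both samples finds itself at distance 0.
    """
    sub = d_union[np.ix_(pos_j, pos_k)]
    return float(
        0.5 * ((w_j * sub.min(axis=1)).sum() + (w_k * sub.min(axis=0)).sum())
    )


def beta_mntd(
    m: CommunityMatrix,
    t: PhyloTree,
    pair: tuple,
    abundance_weighted: bool = True,
    missing_taxa: str = "error",
) -> float:
    """Observed betaMNTD between one pair of samples."""
    m = _check_tree_coverage(m, t, missing_taxa)
    j, k = pair
    col_j = m.data[j]
    col_k = m.data[k]
    taxa_j = list(col_j.index[col_j > 0])
    taxa_k = list(col_k.index[col_k > 0])
    if not taxa_j or not taxa_k:
        raise ValueError("both samples must be nonempty")
    union = sorted(set(taxa_j) | set(taxa_k))
    d_union = np.asarray(patristic_distances(t, union).data)
    index = {x: i for i, x in enumerate(union)}
    pos_j = np.array([index[x] for x in taxa_j])
    pos_k = np.array([index[x] for x in taxa_k])
    if abundance_weighted:
        w_j = col_j[taxa_j].to_numpy(float)
        w_k = col_k[taxa_k].to_numpy(float)
    else:
        w_j = np.ones(len(taxa_j))
        w_k = np.ones(len(taxa_k))
    w_j = w_j / w_j.sum()
    w_k = w_k / w_k.sum()
    return _beta_mntd_core(d_union, pos_j, pos_k, w_j, w_k)


def _pair_list(sample_ids, pairs):
    if pairs is None:
        return list(combinations(sample_ids, 2))
    return [tuple(p) for p in pairs]


def beta_nti(
    m: CommunityMatrix,
    t: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    pairs=None,
    abundance_weighted: bool = True,
    null_scope: str = "pair_union",
    missing_taxa: str = "error",
) -> pd.DataFrame:
    """betaNTI for all (or selected) sample pairs.

    The null shuffles which tips the taxa occupy; by default the shuffle is
    restricted to the union of taxa present in the focal pair
    (``null_scope="pair_union"``), with ``"all_taxa"`` shuffling across
    every taxon in the matrix.  betaNTI = (obs - mean_null) / sd_null; a
    degenerate null (sd 0, e.g. identical communities) yields NaN with a
    warning.  Union taxa are processed in sorted order, so the result does
    not depend on the row order of the input matrix.
    """
    if null_scope not in ("pair_union", "all_taxa"):
        raise ValueError("null_scope must be 'pair_union' or 'all_taxa'")
    m = _check_tree_coverage(m, t, missing_taxa)
    taxa = sorted(m.taxon_ids)
    d_full = np.asarray(patristic_distances(t, taxa).data)
    tindex = {x: i for i, x in enumerate(taxa)}
    counts = m.data
    rng = np.random.default_rng(seed)
    rows = []
    for j, k in _pair_list(m.sample_ids, pairs):
        col_j, col_k = counts[j], counts[k]
        taxa_j = sorted(col_j.index[col_j > 0])
        taxa_k = sorted(col_k.index[col_k > 0])
        if not taxa_j or not taxa_k:
            raise ValueError(f"empty sample in pair ({j}, {k})")
        union = sorted(set(taxa_j) | set(taxa_k))
        u = len(union)
        if null_scope == "pair_union":
            scope_idx = np.array([tindex[x] for x in union])
        else:
            scope_idx = np.arange(len(taxa))
        d_scope = d_full[np.ix_(scope_idx, scope_idx)]
        scope_pos = {taxa[g]: i for i, g in enumerate(scope_idx)}
        pos_j = np.array([scope_pos[x] for x in taxa_j])
        pos_k = np.array([scope_pos[x] for x in taxa_k])
        # union members' positions within the scope, used for shuffling
        union_pos = np.array([scope_pos[x] for x in union])
        rel_j = np.searchsorted(union_pos, pos_j)
        rel_k = np.searchsorted(union_pos, pos_k)
        if abundance_weighted:
            w_j = col_j[taxa_j].to_numpy(float)
            w_k = col_k[taxa_k].to_numpy(float)
        else:
            w_j = np.ones(len(taxa_j))
            w_k = np.ones(len(taxa_k))
        w_j = w_j / w_j.sum()
        w_k = w_k / w_k.sum()
        obs = _beta_mntd_core(d_scope, pos_j, pos_k, w_j, w_k)
        nulls = np.empty(n_null)
        n_scope = d_scope.shape[0]
        for it in range(n_null):
            # place the union's taxa on a random subset of scope tips
            target = (
                rng.permutation(n_scope)[:u]
                if null_scope == "all_taxa"
                else rng.permutation(u)
            )
            if null_scope == "pair_union":
                target = union_pos[target]
            nulls[it] = _beta_mntd_core(
                d_scope, target[rel_j], target[rel_k], w_j, w_k
            )
        null_mean = float(nulls.mean())
        null_sd = float(nulls.std(ddof=1))
        if null_sd > 0:
            bnti = (obs - null_mean) / null_sd
        else:
            warnings.warn(
                f"degenerate null (sd 0) for pair ({j}, {k}); betaNTI undefined",
                stacklevel=2,
            )
            bnti = np.nan
        rows.append(
            {
                "sample_i": j,
                "sample_j": k,
                "beta_mntd": obs,
                "null_mean": null_mean,
                "null_sd": null_sd,
                "bnti": bnti,
            }
        )
    return pd.DataFrame(rows)


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def rc_bray(
    m: CommunityMatrix,
    pair: tuple,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Raup-Crick index on Bray-Curtis for one sample pair, in [-1, 1].

    Each null community keeps the observed richness (taxa drawn without
    replacement with probability proportional to occurrence frequency
    across all samples) and the observed total abundance (each drawn taxon
    receives one individual, the remainder filled multinomially by regional
    relative abundance).  RC = ((#{null BC < obs} + ties/2) / n_null - 0.5)
    * 2, so -1 means the pair is far more similar than the null expects.
    """
    counts = m.counts()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("RC_Bray needs (rarefied) integer counts")
    counts = np.round(counts).astype(np.int64)
    sample_index = {s: i for i, s in enumerate(m.sample_ids)}
    j, k = pair
    xj = counts[:, sample_index[j]]
    xk = counts[:, sample_index[k]]
    if xj.sum() == 0 or xk.sum() == 0:
        raise ValueError("both samples must be nonempty")
    occ = (counts > 0).sum(axis=1).astype(float)
    regional = counts.sum(axis=1).astype(float)
    p_occ = occ / occ.sum()
    obs = _bray_curtis_pair(xj.astype(float), xk.astype(float))
    rng = np.random.default_rng(seed)
    n_taxa = counts.shape[0]

    def null_sample(template: np.ndarray) -> np.ndarray:
        richness = int((template > 0).sum())
        total = int(template.sum())
        chosen = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
        out = np.zeros(n_taxa)
        out[chosen] = 1.0
        if total > richness:
            p_fill = regional[chosen]
            p_fill = p_fill / p_fill.sum()
            out[chosen] += rng.multinomial(total - richness, p_fill)
        return out

    below = ties = 0
    for _ in range(n_null):
        bc = _bray_curtis_pair(null_sample(xj), null_sample(xk))
        if bc < obs:
            below += 1
        elif bc == obs:
            ties += 1
    return float(((below + 0.5 * ties) / n_null - 0.5) * 2.0)


def classify_process(bnti: float, rc: float) -> str:
    """Five-way ecological process label from (betaNTI, RC_Bray).

    Selection first: betaNTI < -2 homogeneous, > +2 heterogeneous (exactly
    +/-2 counts as stochastic).  Otherwise RC_Bray decides: > 0.95
    dispersal limitation, < -0.95 homogenizing dispersal, else undominated.
    A missing betaNTI yields "unclassified".
    """
    if bnti is None or (isinstance(bnti, float) and np.isnan(bnti)):
        return "unclassified"
    if bnti < -2:
        return "homogeneous selection"
    if bnti > 2:
        return "heterogeneous selection"
    if rc is None or (isinstance(rc, float) and np.isnan(rc)):
        return "unclassified"
    if rc > 0.95:
        return "dispersal limitation"
    if rc < -0.95:
        return "homogenizing dispersal"
    return "undominated"


def assembly_analysis(
    m: CommunityMatrix,
    t: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    pairs=None,
    abundance_weighted: bool = True,
    null_scope: str = "pair_union",
    missing_taxa: str = "error",
    compute_rc: bool = True,
) -> AssemblyResult:
    """betaNTI + RC_Bray for all pairs, with per-pair process labels."""
    m = _check_tree_coverage(m, t, missing_taxa)
    table = beta_nti(
        m,
        t,
        n_null=n_null,
        seed=seed,
        pairs=pairs,
        abundance_weighted=abundance_weighted,
        null_scope=null_scope,
    )
    if compute_rc:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        rc_values = []
        for _, row in table.iterrows():
            pair_seed = int(rng.integers(0, 2**31 - 1))
            rc_values.append(
                rc_bray(
                    m, (row["sample_i"], row["sample_j"]), n_null, pair_seed
                )
            )
        table["rc_bray"] = rc_values
    else:
        table["rc_bray"] = np.nan
    table["process"] = [
        classify_process(b, r) for b, r in zip(table["bnti"], table["rc_bray"])
    ]
    return AssemblyResult(table)


def process_summary(
    result: AssemblyResult,
    meta: SampleMetadata,
    group_by: str = "compartment",
) -> pd.DataFrame:
    """Per-group process percentages over within-group sample pairs.

    For each level of ``group_by``, pairs whose two samples both belong to
    the level are tallied into percentages per process label (summing to
    100 within rounding), plus the deterministic fraction
    (|betaNTI| > 2, the two selection labels combined).
    """
    labels = meta.factor(group_by)
    table = result.pairs
    rows = []
    for level in pd.unique(labels):
        members = set(labels.index[labels == level])
        if len(members) < 2:
            warnings.warn(
                f"group {level!r} has < 2 samples; skipped", stacklevel=2
            )
            continue
        sub = table[
            table["sample_i"].isin(members) & table["sample_j"].isin(members)
        ]
        if sub.empty:
            warnings.warn(
                f"no within-group pairs for {level!r}; skipped", stacklevel=2
            )
            continue
        row = {group_by: level, "n_pairs": len(sub)}
        for lab in PROCESS_LABELS:
            row[lab] = 100.0 * (sub["process"] == lab).mean()
        bnti = sub["bnti"].dropna()
        row["deterministic_fraction"] = (
            float(100.0 * (bnti.abs() > 2).mean()) if len(bnti) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
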