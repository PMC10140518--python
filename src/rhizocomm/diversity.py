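"""Alpha/beta diversity, ordination and group comparison.

Conventions follow common practice for 16S OTU tables: Shannon in nats,
Simpson as the unbiased dominance form D = sum n_i(n_i-1) / (N(N-1))
(small values = diverse, anti-correlated with Shannon), Chao1 in the
bias-corrected form, ACE with the rare/abundant cutoff at 10.  Richness
estimators refuse non-integer input because they are undefined on
normalized data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from rhizocomm.matrix import CommunityMatrix, SampleMetadata


# -- alpha diversity -------------------------------------------------------

def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float).ravel()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _as_int_counts(counts) -> np.ndarray:
    arr = _as_counts(counts)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("estimator requires raw integer counts")
    return np.round(arr).astype(np.int64)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), over nonzero taxa."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total <= 0:
        raise ValueError("need at least one positive count")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Unbiased Simpson dominance D = sum n_i(n_i-1) / (N(N-1)).

    D is the probability that two individuals drawn without replacement
    belong to the same taxon; lower values mean higher diversity.
    """
    arr = _as_int_counts(counts)
    total = arr.sum()
    if total < 2:
        raise ValueError("Simpson needs a total count of at least 2")
    return float((arr * (arr - 1)).sum() / (total * (total - 1)))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; the +1 form is used uniformly so
    samples without doubletons never divide by zero.
    """
    arr = _as_int_counts(counts)
    arr = arr[arr > 0]
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based Coverage Estimator with rare cutoff ``rare_threshold``.

    ACE = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2 with sample
    coverage C_ace = 1 - F1 / N_rare and the coefficient of variation
    gamma^2 = max(0, S_rare/C_ace * sum i(i-1)F_i / (N_rare(N_rare-1)) - 1).
    When every rare taxon is a singleton (C_ace = 0) the estimator is
    undefined and Chao1 is returned with a warning.
    """
    arr = _as_int_counts(counts)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("need at least one positive count")
    rare = arr[arr <= rare_threshold]
    s_abund = int((arr > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0:
        warnings.warn(
            "all rare taxa are singletons; ACE undefined, falling back to Chao1",
            stacklevel=2,
        )
        return chao1(counts)
    freqs = np.bincount(rare, minlength=rare_threshold + 1)
    i = np.arange(freqs.size)
    sum_term = float((i * (i - 1) * freqs).sum())
    gamma2 = max(
        0.0, (s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1)) - 1.0
    )
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def alpha_diversity_table(m: CommunityMatrix) -> pd.DataFrame:
    """Per-sample alpha indices (computed on rarefied/raw integer counts)."""
    rows = {}
    for sid in m.sample_ids:
        col = m.data[sid].to_numpy()
        rows[sid] = {
            "observed": int((col > 0).sum()),
            "shannon": shannon(col),
            "simpson": simpson(col),
            "chao1": chao1(col),
            "ace": ace(col),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# -- beta diversity and ordination ----------------------------------------

def bray_curtis(m: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(j,k) = sum|x_j - x_k| / sum(x_j + x_k)."""
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = m.counts().T  # samples x taxa
    if (x.sum(axis=1) == 0).any():
        empty = [s for s, tot in zip(m.sample_ids, x.sum(axis=1)) if tot == 0]
        raise ValueError(f"all-zero samples have undefined Bray-Curtis: {empty}")
    from scipy.spatial.distance import pdist

    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in m.sample_ids])


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per retained (positive) axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical PCoA: eigendecomposition of the double-centered -D^2/2.

    All eigenvalues are reported (negative ones arise for non-Euclidean
    dissimilarities such as Bray-Curtis); coordinate axes are kept only for
    positive eigenvalues, and explained proportions are relative to the sum
    of positive eigenvalues.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((gram + gram.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval).max())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    props = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    labels = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    frame = pd.DataFrame(coords, index=list(d.ids), columns=labels)
    return OrdinationResult(frame, eigval, props)


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, levels) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lev in levels:
        idx = np.flatnonzero(labels == lev)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    meta: SampleMetadata,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with seeded label permutations.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) with sums of squared
    distances; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is
    lower-bounded by 1/(n_perm + 1).
    """
    ids = list(d.ids)
    labels = meta.factor(factor).reindex(ids)
    if labels.isna().any():
        missing = [i for i, v in zip(ids, labels) if pd.isna(v)]
        raise ValueError(f"samples without metadata: {missing}")
    labels = labels.to_numpy()
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2 or (counts < 2).any():
        raise ValueError(
            f"factor {factor!r} needs >= 2 levels with >= 2 samples each"
        )
    a, n = len(levels), len(ids)
    d2 = np.asarray(d.data, dtype=float) ** 2

    ss_total, ss_within = _permanova_ss(d2, labels, levels)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, ss_w = _permanova_ss(d2, perm, levels)
        if ss_w <= 0:
            f_perm = np.inf
        else:
            f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(factor, float(f_obs), float(r2), float(p), n_perm)


def alpha_anova(values: pd.Series, meta: SampleMetadata) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA: compartment, stage and interaction."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = meta.table.copy()
    df["value"] = df["sample_id"].map(values)
    model = smf.ols("value ~ C(compartment) * C(stage)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


# -- group comparison (Tukey letters + Mann-Whitney/Bonferroni) ------------

@dataclass
class GroupComparison:
    letters: dict  # group -> significance letters (Tukey HSD, alpha 0.05)
    tukey: pd.DataFrame  # pairwise Tukey table
    mannwhitney: pd.DataFrame  # pairwise MW p-values, Bonferroni-adjusted


def _letter_display(groups: list, means: dict, distinct: set) -> dict:
    """Compact letter display via the insert-and-absorb algorithm.

    ``distinct`` holds unordered pairs judged significantly different;
    groups sharing a letter are statistically indistinguishable.
    """
    order = sorted(groups, key=lambda g: -means[g])
    sets = [set(order)]
    for g1, g2 in distinct:
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.extend([s - {g1}, s - {g2}])
        # absorb subsets
        sets = [
            s
            for s in sets
            if s and not any(s < other for other in sets if other is not s)
        ]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return letters


def group_compare(
    values: pd.Series,
    meta: SampleMetadata,
    factor: str = "compartment",
    stratify_by: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Tukey HSD letters and Bonferroni-corrected Mann-Whitney per stratum.

    ``values`` is indexed by sample id.  With ``stratify_by="stage"`` the
    comparison across compartments is run separately within each stage —
    the layout of a per-stage index table.  Returns
    ``{stratum: GroupComparison}`` (stratum ``None`` when unstratified).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = meta.table.copy()
    df["value"] = df["sample_id"].map(values).astype(float)
    strata = (
        [(None, df)]
        if stratify_by is None
        else list(df.groupby(stratify_by, sort=False))
    )
    out = {}
    for stratum, sub in strata:
        groups = list(pd.unique(sub[factor]))
        sizes = sub.groupby(factor)["value"].size()
        if len(groups) < 2 or (sizes < 2).any():
            raise ValueError(
                f"stratum {stratum!r}: need >= 2 groups with >= 2 replicates"
            )
        means = sub.groupby(factor)["value"].mean().to_dict()
        if np.allclose(sub["value"].var(ddof=0), 0.0):
            warnings.warn(
                f"constant values in stratum {stratum!r}; "
                "no significant differences",
                stacklevel=2,
            )
            letters = {g: "a" for g in groups}
            tukey_df = pd.DataFrame(
                columns=["group1", "group2", "meandiff", "p_adj", "reject"]
            )
            mw_df = pd.DataFrame(columns=["group1", "group2", "p_raw", "p_bonf"])
            out[stratum] = GroupComparison(letters, tukey_df, mw_df)
            continue
        res = pairwise_tukeyhsd(sub["value"], sub[factor], alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:],
            columns=[str(c) for c in res.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
        distinct = {
            frozenset((row["group1"], row["group2"]))
            for _, row in tukey_df.iterrows()
            if bool(row["reject"])
        }
        letters = _letter_display(groups, means, distinct)

        pairs = [
            (groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
        mw_rows = []
        for g1, g2 in pairs:
            u = stats.mannwhitneyu(
                sub.loc[sub[factor] == g1, "value"],
                sub.loc[sub[factor] == g2, "value"],
                alternative="two-sided",
            )
            mw_rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "p_raw": u.pvalue,
                    "p_bonf": min(1.0, u.pvalue * len(pairs)),
                }
            )
        out[stratum] = GroupComparison(letters, tukey_df, pd.DataFrame(mw_rows))
    return out


def percent_increase(a: float, b: float) -> float:
    """Percent change of ``a`` relative to baseline ``b``, to 2 decimals."""
    if b <= 0:
        raise ValueError("baseline must be > 0")
    return round(100.0 * (a - b) / b, 2)
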