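"""Rule-based functional-group annotation and its PCA summary.

A rule file maps functional groups (nitrification, chemoheterotrophy, ...)
to lineage patterns.  The line-oriented format is a compatible subset of
the FAPROTAX database format, so users can supply the full database;
only a miniature synthetic rule set ships with the test suite.

Format::

    nitrification:
        *Nitrospira*
        -*Candidatus_Nitrotoga*   # exclusion

A group header ends with ":"; indented lines are wildcard patterns matched
(case-sensitively, fnmatch semantics) against the semicolon-joined lineage
"kingdom;phylum;class;order;family;genus".  A taxon contributes its full
abundance to every group with a matching pattern and no matching
exclusion, so overlapping groups may sum to more than the sample total.
"""

from __future__ import annotations

from dataclasses import dataclass
from fnmatch import fnmatchcase
from pathlib import Path

import numpy as np
import pandas as pd

from rhizocomm.matrix import CommunityMatrix, TaxonomyTable


class RuleError(ValueError):
    pass


@dataclass
class FunctionRule:
    group: str
    patterns: list[str]
    exclusions: list[str]

    def matches(self, lineage: str) -> bool:
        if any(fnmatchcase(lineage, pat) for pat in self.exclusions):
            return False
        return any(fnmatchcase(lineage, pat) for pat in self.patterns)


@dataclass
class FunctionTable:
    """Functional group x sample abundances with full provenance."""

    table: pd.DataFrame  # groups x samples
    provenance: dict  # group -> {taxon_id: abundance row (per sample)}

    @property
    def groups(self) -> list:
        return list(self.table.index)

    def check_provenance(self) -> bool:
        """Summing provenance contributions must reproduce the table."""
        for group in self.table.index:
            contribs = self.provenance.get(group, {})
            total = np.zeros(self.table.shape[1])
            for row in contribs.values():
                total = total + np.asarray(row, dtype=float)
            if not np.allclose(total, self.table.loc[group].to_numpy()):
                return False
        return True


def parse_rules(source) -> list[FunctionRule]:
    """Parse a rule file (path or literal text); malformed lines raise
    with their line number."""
    text = str(source)
    if text and "\n" not in text and Path(text).is_file():
        text = Path(text).read_text()
    rules: list[FunctionRule] = []
    current: FunctionRule | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        indented = line[0] in (" ", "\t")
        body = line.strip()
        if not indented:
            if not body.endswith(":"):
                raise RuleError(
                    f"line {lineno}: expected 'group:' header, got {body!r}"
                )
            name = body[:-1].strip()
            if not name:
                raise RuleError(f"line {lineno}: empty group name")
            current = FunctionRule(name, [], [])
            rules.append(current)
        else:
            if current is None:
                raise RuleError(
                    f"line {lineno}: pattern before any group header"
                )
            if body.startswith("-"):
                pat = body[1:].strip()
                if not pat:
                    raise RuleError(f"line {lineno}: empty exclusion pattern")
                current.exclusions.append(pat)
            else:
                current.patterns.append(body)
    return rules


def annotate_functions(
    taxonomy: TaxonomyTable,
    m: CommunityMatrix,
    rules: list[FunctionRule] | str,
) -> FunctionTable:
    """Assign taxon abundances to functional groups by lineage matching.

    Every assigned abundance is traceable: the provenance maps each group
    to the per-sample contribution of each matched taxon.  Groups with no
    matches are present as all-zero rows.
    """
    if isinstance(rules, (str, Path)):
        rules = parse_rules(rules)
    lineages = taxonomy.lineages()
    rel = m.relative_abundance().data
    samples = list(rel.columns)
    data = {}
    provenance: dict[str, dict] = {}
    for rule in rules:
        row = np.zeros(len(samples))
        contribs = {}
        for taxon in rel.index:
            lineage = lineages.get(taxon)
            if lineage is None:
                continue
            if rule.matches(lineage):
                contribution = rel.loc[taxon].to_numpy(float)
                row = row + contribution
                contribs[taxon] = contribution.tolist()
        data[rule.group] = row
        provenance[rule.group] = contribs
    table = pd.DataFrame(data, index=samples).T
    table.index.name = "functional_group"
    return FunctionTable(table, provenance)


@dataclass
class FunctionOrdination:
    scores: pd.DataFrame  # samples x PCs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    zscored: pd.DataFrame  # row-z-scored group x sample matrix (heatmap)


def function_ordination(
    f: FunctionTable, scale: bool = False
) -> FunctionOrdination:
    """PCA of samples in functional-group space, plus a heatmap matrix.

    The group x sample table is transposed to samples x groups, centered
    (optionally unit-scaled) and decomposed by SVD.  The z-scored matrix
    standardizes each group row to mean 0, sd 1 for heatmap display
    (constant rows are left at 0).
    """
    x = f.table.T.to_numpy(float)  # samples x groups
    n, g = x.shape
    if n < 2 or g < 2:
        raise ValueError("need at least 2 samples and 2 groups")
    centered = x - x.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    if np.allclose(centered, 0):
        raise ValueError("zero variance everywhere; PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    var = s**2 / (n - 1)
    keep = var > 1e-12 * var.max()
    scores = scores[:, keep]
    var = var[keep]
    frame = pd.DataFrame(
        scores,
        index=f.table.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    row_mean = f.table.mean(axis=1)
    row_sd = f.table.std(axis=1, ddof=1).replace(0, np.nan)
    z = f.table.sub(row_mean, axis=0).div(row_sd, axis=0).fillna(0.0)
    return FunctionOrdination(frame, var, var / var.sum(), z)
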