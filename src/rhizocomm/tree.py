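"""Rooted phylogeny wrapper and patristic distances.

Trees are held as :class:`dendropy.Tree` objects; tip labels are taxon ids.
Patristic (path-length) distances feed the betaMNTD/betaNTI stage, which
errors by default when matrix taxa are missing from the tree — silent
pruning would corrupt the phylogenetic turnover statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Rooted tree with non-negative branch lengths and unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(
                    f"negative branch length on edge above "
                    f"{edge.head_node.taxon or 'internal node'}"
                )

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse Newick from a path or a literal string."""
        text = str(source)
        looks_like_newick = "(" in text and text.rstrip().endswith(";")
        if not looks_like_newick:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise TreeError(f"invalid newick: {exc}") from exc
        return cls(tree)

    def to_newick(self, path=None) -> str:
        s = self.tree.as_string(
            schema="newick", unquoted_underscores=True
        ).strip()
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def prune_to(self, taxa) -> "PhyloTree":
        """Retain only the given tips (explicit, never done implicitly)."""
        taxa = list(taxa)
        known = set(self.tip_labels)
        unknown = [t for t in taxa if t not in known]
        if unknown:
            raise TreeError(f"taxa not on the tree: {unknown}")
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(taxa)
        return PhyloTree(clone)

    def root_to_tip_lengths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = np.array(list(self.root_to_tip_lengths().values()))
        return bool(np.ptp(depths) <= tol * max(1.0, depths.max()))


def patristic_distances(t: PhyloTree, taxa=None) -> DistanceMatrix:
    """Patristic distance matrix for ``taxa`` (default: all tips).

    The distance between two tips is the sum of branch lengths on the path
    connecting them; the result is a symmetric, zero-diagonal matrix that
    satisfies the triangle inequality.
    """
    if taxa is None:
        taxa = t.tip_labels
    taxa = list(taxa)
    known = set(t.tip_labels)
    unknown = [x for x in taxa if x not in known]
    if unknown:
        raise TreeError(f"taxa not on the tree: {unknown}")
    pdm = t.tree.phylogenetic_distance_matrix()
    label_to_taxon = {
        tx.label: tx for tx in t.tree.taxon_namespace if tx.label in set(taxa)
    }
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        ti = label_to_taxon[taxa[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(ti, label_to_taxon[taxa[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=[str(x) for x in taxa])
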