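"""Community matrix, metadata and taxonomy containers plus shared primitives.

The central object is :class:`CommunityMatrix`, a taxa-rows x sample-columns
table of counts or relative abundances.  All downstream stages consume this
orientation and document it.  Normalization (rarefaction) and prevalence
filtering live here because several stages share them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COMPARTMENTS = ("bulk", "rhizosphere", "rhizoplane")
STAGES = ("tillering", "heading", "mature")

#: canonical rank order for taxonomy lineages
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: explicit marker for a missing rank (never silently dropped)
MISSING_RANK = ""


class CommunityMatrixError(ValueError):
    """Raised when a community table violates a structural invariant."""


@dataclass
class CommunityMatrix:
    """Taxa x samples abundance table.

    Parameters
    ----------
    data:
        DataFrame with taxa as the index and samples as columns.  Values are
        non-negative counts or relative abundances.
    semantics:
        One of ``"raw"`` (integer counts), ``"normalized"`` (rarefied counts)
        or ``"relative"`` (columns sum to one).
    """

    data: pd.DataFrame
    semantics: str = "raw"

    def __post_init__(self) -> None:
        if self.semantics not in ("raw", "normalized", "relative"):
            raise CommunityMatrixError(
                f"unknown semantics {self.semantics!r}; expected raw, "
                "normalized or relative"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise CommunityMatrixError(f"duplicate taxon ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise CommunityMatrixError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            cell = next(zip(*np.nonzero(bad.to_numpy())), None)
            where = (
                f" (taxon {idx[cell[0]]!r}, sample {cols[cell[1]]!r})"
                if cell
                else ""
            )
            raise CommunityMatrixError(f"non-numeric cell{where}")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise CommunityMatrixError(
                f"non-numeric cell (taxon {idx[r]!r}, sample {cols[c]!r})"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise CommunityMatrixError(
                f"negative value at (taxon {idx[r]!r}, sample {cols[c]!r})"
            )
        if self.semantics == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise CommunityMatrixError(
                    "relative-abundance columns must each sum to 1"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        """Values as a dense (taxa x samples) float array."""
        return self.data.to_numpy(dtype=float)

    def zero_taxa(self) -> list:
        """Taxa whose row is all zero (representable but flagged)."""
        row_sums = self.data.sum(axis=1)
        return list(row_sums.index[row_sums == 0])

    def relative_abundance(self) -> "CommunityMatrix":
        """Column-normalize to relative abundances."""
        sums = self.data.sum(axis=0)
        if (sums == 0).any():
            empty = list(sums.index[sums == 0])
            raise CommunityMatrixError(f"all-zero samples: {empty}")
        return CommunityMatrix(self.data / sums, semantics="relative")

    def select_samples(self, sample_ids) -> "CommunityMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise CommunityMatrixError(f"unknown sample ids: {missing}")
        return CommunityMatrix(self.data[list(sample_ids)], self.semantics)


@dataclass
class SampleMetadata:
    """Per-sample design factors: compartment, growth stage, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "compartment", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise CommunityMatrixError(
                f"metadata missing columns: {sorted(missing)}"
            )
        if self.table["sample_id"].duplicated().any():
            dups = self.table["sample_id"][
                self.table["sample_id"].duplicated()
            ].tolist()
            raise CommunityMatrixError(f"duplicate metadata sample ids: {dups}")
        bad_comp = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise CommunityMatrixError(
                f"unknown compartment levels: {sorted(bad_comp)}; "
                f"allowed: {COMPARTMENTS}"
            )
        bad_stage = set(self.table["stage"]) - set(STAGES)
        if bad_stage:
            raise CommunityMatrixError(
                f"unknown stage levels: {sorted(bad_stage)}; allowed: {STAGES}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def factor(self, name: str) -> pd.Series:
        """Factor levels indexed by sample id."""
        if name not in self.table.columns:
            raise KeyError(f"unknown factor {name!r}")
        return self.table.set_index("sample_id")[name]

    def check_matches(self, m: CommunityMatrix) -> None:
        """Every matrix sample must have exactly one metadata row."""
        meta_ids = set(self.sample_ids)
        missing = [s for s in m.sample_ids if s not in meta_ids]
        if missing:
            raise CommunityMatrixError(
                f"samples without metadata: {missing}"
            )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


@dataclass
class TaxonomyTable:
    """Ranked lineages (kingdom..genus) per taxon; missing ranks explicit."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "taxon_id" not in self.table.columns:
            raise CommunityMatrixError("taxonomy table needs a taxon_id column")
        for rank in RANKS:
            if rank not in self.table.columns:
                self.table[rank] = MISSING_RANK
        if self.table["taxon_id"].duplicated().any():
            raise CommunityMatrixError("duplicate taxon ids in taxonomy")
        self.table = self.table.fillna(MISSING_RANK).reset_index(drop=True)

    def phylum(self) -> pd.Series:
        """Phylum per taxon id; missing phyla stay as the empty marker."""
        return self.table.set_index("taxon_id")["phylum"]

    def lineage(self, taxon_id) -> str:
        """Semicolon-joined lineage string (used by rule matching)."""
        row = self.table.loc[self.table["taxon_id"] == taxon_id]
        if row.empty:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        return ";".join(str(row.iloc[0][r]) for r in RANKS)

    def lineages(self) -> pd.Series:
        joined = self.table[list(RANKS)].astype(str).agg(";".join, axis=1)
        return pd.Series(joined.values, index=self.table["taxon_id"].values)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


# -- I/O -------------------------------------------------------------------

def read_community_matrix(path, format: str = "tsv") -> CommunityMatrix:
    """Read a taxa x samples table from TSV or BIOM-style JSON.

    TSV layout: header row of sample ids, first column taxon ids.  Row and
    column order are preserved.  Duplicate ids, negative or non-numeric
    cells are hard errors naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dups = sorted({h for h in header if header.count(h) > 1})
        if dups:
            raise CommunityMatrixError(f"duplicate sample ids: {dups}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "taxon_id"
        return CommunityMatrix(df)
    if format == "biom":
        doc = json.loads(path.read_text())
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        dense = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                dense[r, c] = v
        else:
            dense[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(dense, index=taxa, columns=samples)
        df.index.name = "taxon_id"
        return CommunityMatrix(df)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_community_matrix(m: CommunityMatrix, path, format: str = "tsv") -> None:
    """Write a community matrix; TSV round-trips values bitwise."""
    path = Path(path)
    if format == "tsv":
        df = m.data.copy()
        if m.semantics != "relative" and np.allclose(
            df.to_numpy(), np.round(df.to_numpy())
        ):
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t", index_label="taxon_id")
        return
    if format == "biom":
        values = m.data.to_numpy()
        rows, cols = np.nonzero(values)
        doc = {
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "shape": list(values.shape),
            "rows": [{"id": str(t), "metadata": None} for t in m.taxon_ids],
            "columns": [{"id": str(s), "metadata": None} for s in m.sample_ids],
            "data": [
                [int(r), int(c), float(values[r, c])] for r, c in zip(rows, cols)
            ],
        }
        path.write_text(json.dumps(doc))
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


# -- normalization and filtering ------------------------------------------

def normalize_depth(m: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Rarefy each sample to ``depth`` reads without replacement.

    Each column is subsampled hypergeometrically (equivalent to drawing
    ``depth`` individuals without replacement), so every output column sums
    exactly to ``depth``.  Reproducible under ``seed``.
    """
    if m.semantics == "relative":
        raise CommunityMatrixError("rarefaction needs raw counts")
    counts = m.counts()
    if not np.allclose(counts, np.round(counts)):
        raise CommunityMatrixError("rarefaction needs integer counts")
    counts = np.round(counts).astype(np.int64)
    col_sums = counts.sum(axis=0)
    too_shallow = [
        s for s, tot in zip(m.sample_ids, col_sums) if tot < depth
    ]
    if too_shallow:
        raise CommunityMatrixError(
            f"depth {depth} exceeds total counts of samples: {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return CommunityMatrix(df, semantics="normalized")


def prevalence_filter(m: CommunityMatrix, min_fraction: float) -> CommunityMatrix:
    """Keep taxa present in strictly more than ``min_fraction`` of samples.

    Presence means count > 0.  The comparison is strict ("over" the
    threshold), so a taxon in exactly half the samples is removed at
    ``min_fraction=0.5``.  The sample set is unchanged.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    presence = (m.data > 0).sum(axis=1) / m.shape[1]
    keep = presence > min_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return CommunityMatrix(m.data.loc[keep], m.semantics)
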