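"""Count-matrix container, readers/writers, QC filters and pseudobulk.

Raw UMI counts are held genes x cells in a sparse matrix with aligned
gene and cell annotation tables, mirroring the CellRanger-style triplet
on disk (MatrixMarket coordinate file + genes.tsv + cells.tsv with
1-based indices in the MTX).

The quality-control pipeline applied before model training is:

1. subset to genes with one-to-one orthologs across all species,
2. drop mitochondrial genes,
3. drop cells with fewer than 200 total UMIs,
4. drop genes expressed (count > 0) in fewer than 50 cells, counted
   across the full concatenated multi-dataset matrix.

Applying the full pipeline twice changes nothing (idempotence is a
tested property).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("crosscell")

CELL_COLUMNS = ("cell_id", "species", "batch", "tissue", "donor")


@dataclass
class CountMatrix:
    """Sparse gene-by-cell raw UMI counts with aligned annotation tables.

    Attributes
    ----------
    values
        ``scipy.sparse`` matrix, genes x cells, non-negative integers.
    genes
        DataFrame with at least ``gene_id``; optional per-species
        chromosome columns, ``is_mito``, ``is_housekeeping``.
    cells
        DataFrame with ``cell_id`` plus metadata columns
        (species/batch/tissue/donor, optional cell_type).
    """

    values: sp.spmatrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    _depth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = sp.csc_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix is {self.values.shape} but tables describe "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")
        if self.values.nnz and np.any(self.values.data != np.round(self.values.data)):
            raise ValueError("non-integer counts")
        for frame, col in ((self.genes, "gene_id"), (self.cells, "cell_id")):
            if frame[col].duplicated().any():
                dup = frame[col][frame[col].duplicated()].iloc[0]
                raise ValueError(f"duplicate {col}: {dup!r}")
        self.genes = self.genes.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """Per-cell total UMI count (cached)."""
        if self._depth is None:
            self._depth = np.asarray(self.values.sum(axis=0)).ravel()
        return self._depth

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        m = self.values
        genes, cells = self.genes, self.cells
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            m = m[gene_mask, :]
            genes = genes.iloc[gene_mask] if gene_mask.dtype != bool else genes.loc[gene_mask]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            m = m[:, cell_mask]
            cells = cells.iloc[cell_mask] if cell_mask.dtype != bool else cells.loc[cell_mask]
        return CountMatrix(m, genes.reset_index(drop=True), cells.reset_index(drop=True))


@dataclass
class PseudobulkProfile:
    """Per-group mean of depth-normalized per-cell profiles."""

    values: np.ndarray
    group_key: tuple
    n_cells: int
    log_transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_cells < 1:
            raise ValueError("pseudobulk requires at least one cell")
        if not self.log_transformed and (self.values < 0).any():
            raise ValueError("negative pseudobulk values")


# -- reading / writing ---------------------------------------------------


def read_count_matrix(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a MatrixMarket triplet (matrix.mtx + genes.tsv + cells.tsv)."""
    m = sp.csc_matrix(scipy.io.mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    return CountMatrix(m, genes, cells)


def write_count_matrix(m: CountMatrix, outdir, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), sp.coo_matrix(m.values), field="integer")
    m.genes.to_csv(outdir / f"{prefix}genes.tsv", sep="\t", index=False)
    m.cells.to_csv(outdir / f"{prefix}cells.tsv", sep="\t", index=False)


# -- filters -------------------------------------------------------------


def filter_cells_min_umi(m: CountMatrix, min_umi: int = 200) -> CountMatrix:
    """Keep cells with depth >= ``min_umi`` (cells with < min_umi are removed)."""
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    return m.subset(cell_mask=m.depth >= min_umi)


def filter_genes_min_cells(m: CountMatrix, min_cells: int = 50) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells."""
    n_expressing = np.asarray((m.values > 0).sum(axis=1)).ravel()
    return m.subset(gene_mask=n_expressing >= min_cells)


def remove_gene_set(m: CountMatrix, gene_ids: Iterable[str]) -> CountMatrix:
    """Drop the listed genes; unknown IDs are ignored with a warning."""
    gene_ids = set(gene_ids)
    known = set(m.genes["gene_id"])
    missing = gene_ids - known
    if missing:
        logger.warning("remove_gene_set: %d IDs not in matrix (e.g. %s)",
                       len(missing), sorted(missing)[0])
    keep = ~m.genes["gene_id"].isin(gene_ids).to_numpy()
    return m.subset(gene_mask=keep)


def remove_mito(m: CountMatrix) -> CountMatrix:
    """Drop genes flagged mitochondrial (``is_mito`` column, if present)."""
    if "is_mito" not in m.genes.columns:
        return m
    return m.subset(gene_mask=~m.genes["is_mito"].fillna(False).astype(bool).to_numpy())


def apply_qc_pipeline(m: CountMatrix, ortholog_gene_ids: Sequence[str] | None = None,
                      min_umi: int = 200, min_cells: int = 50) -> CountMatrix:
    """Ortholog subset -> mito removal -> cell UMI filter -> gene prevalence filter."""
    if ortholog_gene_ids is not None:
        keep = m.genes["gene_id"].isin(set(ortholog_gene_ids)).to_numpy()
        m = m.subset(gene_mask=keep)
    m = remove_mito(m)
    m = filter_cells_min_umi(m, min_umi)
    m = filter_genes_min_cells(m, min_cells)
    return m


# -- normalisation and pseudobulk ---------------------------------------


def depth_normalize(m: CountMatrix, target: float = 10000.0) -> np.ndarray:
    """Scale each cell so its column sums to ``target``; genes x cells dense."""
    depth = m.depth
    zero = np.flatnonzero(depth == 0)
    if zero.size:
        raise ValueError(
            f"cell {m.cells['cell_id'].iloc[zero[0]]!r} has zero depth; "
            "filter cells before normalizing"
        )
    return np.asarray(m.values.todense()) * (target / depth)


def pseudobulk(m: CountMatrix, group_by: Sequence[str], target: float = 1.0,
               log_transform: bool = False,
               normalized: np.ndarray | None = None) -> list[PseudobulkProfile]:
    """Average depth-normalized profiles within each metadata group.

    ``log_transform`` applies log2(x + 1) after averaging. Pass
    ``normalized`` to reuse a precomputed genes x cells matrix.
    """
    if normalized is None:
        normalized = depth_normalize(m, target=target)
    out = []
    for key, idx in m.cells.groupby(list(group_by), sort=True, observed=True).indices.items():
        if len(idx) == 0:  # pragma: no cover - pandas never yields empty groups
            logger.warning("pseudobulk: empty group %s skipped", key)
            continue
        vals = normalized[:, idx].mean(axis=1)
        if log_transform:
            vals = np.log2(vals + 1.0)
        key = key if isinstance(key, tuple) else (key,)
        out.append(PseudobulkProfile(vals, key, len(idx), log_transformed=log_transform))
    return out
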