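"""Core in-memory containers for the cross-species pipeline.

Expression data is held genes x cells (the orientation of the standard
MatrixMarket deposition for droplet data), with an explicit scale flag so
that delogging is applied exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"

_VALID_SCALES = (RAW_COUNTS, LOGNORM)


class ValidationError(ValueError):
    """Raised when an input matrix or table violates its contract."""


def _check_unique(ids, what: str) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")
    return idx


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with a scale flag.

    Parameters
    ----------
    values
        Dense float array, shape (n_genes, n_cells); non-negative, finite.
    genes, cells
        Unique identifiers for rows and columns.
    scale
        ``"raw_counts"`` for raw-scale (counts or delogged normalized
        values) or ``"lognorm"`` for natural-log of (value + 1).
    """

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (genes x cells)")
        self.genes = _check_unique(self.genes, "gene")
        self.cells = _check_unique(self.cells, "cell")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if (self.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.scale not in _VALID_SCALES:
            raise ValidationError(f"scale must be one of {_VALID_SCALES}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:10])
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(
            self.values[idx, :], pd.Index(genes), self.cells, self.scale
        )

    def rename_genes(self, mapping: dict) -> "ExpressionMatrix":
        new = [mapping.get(g, g) for g in self.genes]
        return ExpressionMatrix(self.values.copy(), pd.Index(new), self.cells, self.scale)


@dataclass
class PseudoProfileMatrix:
    """Aggregated genes x profiles matrix (pseudo-bulk or pseudo-cell).

    ``meta`` has one row per profile with columns ``cell_type``,
    ``dataset`` and ``members`` (tuple of aggregated cell ids).
    """

    values: np.ndarray
    genes: pd.Index
    profiles: pd.Index
    kind: str  # "pseudo_bulk" | "pseudo_cell"
    meta: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = _check_unique(self.genes, "gene")
        self.profiles = _check_unique(self.profiles, "profile")
        if self.values.shape != (len(self.genes), len(self.profiles)):
            raise ValidationError("profile matrix shape mismatch")
        if self.kind not in ("pseudo_bulk", "pseudo_cell"):
            raise ValidationError("kind must be pseudo_bulk or pseudo_cell")
        if self.meta is None:
            raise ValidationError("profile metadata required")
        if not self.meta.index.equals(self.profiles):
            raise ValidationError("meta index must equal profile ids")
        members: list = []
        for m in self.meta["members"]:
            members.extend(m)
        if len(members) != len(set(members)):
            raise ValidationError("a cell may belong to at most one profile")

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.profiles)

    def subset_genes(self, genes) -> "PseudoProfileMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:10])
            raise KeyError(f"genes not in profiles: {missing}")
        return PseudoProfileMatrix(
            self.values[idx, :], pd.Index(genes), self.profiles, self.kind, self.meta
        )


@dataclass
class ScoreMatrix:
    """Cell-type x cell-type score matrix with train/test orientation tags.

    Rows are types of ``row_dataset`` (train side for the stored
    orientation), columns types of ``col_dataset``. ``data`` is a pandas
    DataFrame; missing scores are NaN.
    """

    data: pd.DataFrame
    row_dataset: str
    col_dataset: str
    kind: str = "auroc"  # auroc | enrichment | spearman | conservation

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "row label")
        _check_unique(self.data.columns, "column label")
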