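"""Delogging, pseudo-bulk / pseudo-cell aggregation, Spearman matrices.

The aggregation contract: log-normalized values are first antilogged and
the pseudo-count subtracted (exp(x) - 1), then member cells are averaged
on that raw scale. Pseudo-cells are disjoint random groups of
``group_size`` same-type cells, stratified by (dataset, cell type) so
profiles never mix libraries.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (
    LOGNORM,
    RAW_COUNTS,
    ExpressionMatrix,
    PseudoProfileMatrix,
    ScoreMatrix,
    ValidationError,
)


def lognormalize(matrix: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size scale each cell to ``target_sum`` and apply log1p."""
    if matrix.scale != RAW_COUNTS:
        raise ValidationError("lognormalize expects raw counts")
    totals = matrix.values.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    scaled = matrix.values / totals * target_sum
    return ExpressionMatrix(np.log1p(scaled), matrix.genes, matrix.cells, LOGNORM)


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Invert log1p: elementwise exp(x) - 1, clipped at zero."""
    if matrix.scale != LOGNORM:
        raise ValidationError("delog expects a lognorm matrix")
    vals = np.clip(np.expm1(matrix.values), 0.0, None)
    return ExpressionMatrix(vals, matrix.genes, matrix.cells, RAW_COUNTS)


def _as_raw(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return delog(matrix) if matrix.scale == LOGNORM else matrix


def _check_labels(matrix: ExpressionMatrix, labels: dict) -> None:
    missing = [c for c in matrix.cells if c not in labels]
    if missing:
        raise ValidationError(f"unlabeled cells: {missing[:10]}")


def pseudo_bulk(
    matrix: ExpressionMatrix,
    labels: dict,
    dataset: str = "dataset",
) -> PseudoProfileMatrix:
    """One profile per cell type: per-gene mean of delogged expression."""
    _check_labels(matrix, labels)
    raw = _as_raw(matrix)
    types = sorted({labels[c] for c in matrix.cells})
    cols, meta_rows, ids = [], [], []
    cell_pos = {c: i for i, c in enumerate(matrix.cells)}
    for t in types:
        members = [c for c in matrix.cells if labels[c] == t]
        idx = [cell_pos[c] for c in members]
        cols.append(raw.values[:, idx].mean(axis=1))
        ids.append(f"{dataset}|{t}")
        meta_rows.append({"cell_type": t, "dataset": dataset, "members": tuple(members)})
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids))
    return PseudoProfileMatrix(
        np.column_stack(cols), raw.genes, pd.Index(ids), "pseudo_bulk", meta
    )


def pseudo_cell(
    matrix: ExpressionMatrix,
    labels: dict,
    group_size: int = 10,
    seed: int = 0,
    dataset: str = "dataset",
    libraries: dict | None = None,
) -> PseudoProfileMatrix:
    """Aggregate random disjoint groups of ``group_size`` same-type cells.

    Within each (library, cell type) stratum, cells are shuffled (seeded)
    and chunked; the trailing remainder is dropped unless the stratum is
    smaller than ``group_size``, in which case one undersized group keeps
    the whole stratum so no cell type silently disappears.
    """
    if group_size < 1:
        raise ValidationError("group_size must be >= 1")
    _check_labels(matrix, labels)
    raw = _as_raw(matrix)
    rng = np.random.default_rng(seed)
    cell_pos = {c: i for i, c in enumerate(matrix.cells)}
    libraries = libraries or {}

    strata: dict[tuple[str, str], list] = {}
    for c in matrix.cells:
        strata.setdefault((str(libraries.get(c, "lib0")), labels[c]), []).append(c)

    cols, ids, meta_rows = [], [], []
    for (lib, t) in sorted(strata):
        members = sorted(strata[(lib, t)])  # order-independent before shuffling
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        n = len(shuffled)
        if n < group_size:
            groups = [shuffled]
        else:
            groups = [
                shuffled[k * group_size : (k + 1) * group_size]
                for k in range(n // group_size)
            ]
        for k, grp in enumerate(groups):
            idx = [cell_pos[c] for c in grp]
            cols.append(raw.values[:, idx].mean(axis=1))
            ids.append(f"{dataset}|{lib}|{t}|{k}")
            meta_rows.append(
                {"cell_type": t, "dataset": dataset, "members": tuple(grp)}
            )
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids))
    return PseudoProfileMatrix(
        np.column_stack(cols), raw.genes, pd.Index(ids), "pseudo_cell", meta
    )


def spearman_matrix(
    profiles_a: PseudoProfileMatrix,
    profiles_b: PseudoProfileMatrix,
    genes: list | None = None,
) -> ScoreMatrix:
    """Spearman rank correlation (midrank ties) between all profile pairs."""
    if genes is None:
        genes = [g for g in profiles_a.genes if g in set(profiles_b.genes)]
    genes = list(genes)
    if len(genes) < 3:
        raise ValidationError("need at least 3 shared genes")
    va = profiles_a.subset_genes(genes).values
    vb = profiles_b.subset_genes(genes).values
    ra = stats.rankdata(va, axis=0)
    rb = stats.rankdata(vb, axis=0)

    def _std(m):
        return m.std(axis=0)

    const_a = _std(ra) == 0
    const_b = _std(rb) == 0
    za = (ra - ra.mean(axis=0)) / np.where(const_a, 1.0, _std(ra))
    zb = (rb - rb.mean(axis=0)) / np.where(const_b, 1.0, _std(rb))
    corr = za.T @ zb / len(genes)
    if const_a.any() or const_b.any():
        warnings.warn("constant profile(s): Spearman undefined, set to NaN")
        corr[const_a, :] = np.nan
        corr[:, const_b] = np.nan
    data = pd.DataFrame(corr, index=profiles_a.profiles, columns=profiles_b.profiles)
    ds_a = profiles_a.meta["dataset"].iloc[0] if len(profiles_a.meta) else "A"
    ds_b = profiles_b.meta["dataset"].iloc[0] if len(profiles_b.meta) else "B"
    return ScoreMatrix(data, ds_a, ds_b, kind="spearman")
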