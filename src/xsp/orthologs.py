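"""One-to-one ortholog map resolution.

Candidate ortholog tables (DIOPT-style: weighted score plus a
best-score-reverse flag) are many-to-many. Resolution keeps, for each
gene, the partner with (1) the highest weighted score, (2) the
best-score-reverse flag set, (3) the highest mean expression of the
partner in its own dataset, with fraction-of-cells-expressing and then
lexicographic gene id as final deterministic tie-breaks. Collisions left
by per-gene selection (two A genes electing the same B gene) are settled
greedily in descending confidence order; losers fall back to their next
best candidate until the map is strictly one-to-one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import delog
from .matrix import ExpressionMatrix, ValidationError

CANDIDATE_COLUMNS = ["gene_a", "gene_b", "weighted_score", "best_score_reverse"]

RULE_UNIQUE = "unique"
RULE_SCORE = "score"
RULE_REVERSE = "reverse"
RULE_EXPRESSION = "expression"
RULE_GLOBAL = "global_greedy"


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-gene summary of one species' dataset on the raw (delogged) scale."""

    table: pd.DataFrame  # index gene; columns mean_expr, frac_cells, n_cells_expressing

    def mean(self, gene: str) -> float:
        try:
            return float(self.table.at[gene, "mean_expr"])
        except KeyError:
            return 0.0

    def frac(self, gene: str) -> float:
        try:
            return float(self.table.at[gene, "frac_cells"])
        except KeyError:
            return 0.0

    def n_expressing(self, gene: str) -> int:
        try:
            return int(self.table.at[gene, "n_cells_expressing"])
        except KeyError:
            return 0


def expression_summary(matrix: ExpressionMatrix) -> ExpressionSummary:
    """Mean delogged expression and detection fraction per gene."""
    if matrix.scale == "lognorm":
        matrix = delog(matrix)
    vals = matrix.values
    n = matrix.n_cells
    expressing = (vals > 0).sum(axis=1)
    tab = pd.DataFrame(
        {
            "mean_expr": vals.mean(axis=1),
            "frac_cells": expressing / n if n else 0.0,
            "n_cells_expressing": expressing,
        },
        index=matrix.genes,
    )
    return ExpressionSummary(tab)


@dataclass
class OrthologMap:
    """Strict one-to-one gene pairs with the resolution rule per pair."""

    table: pd.DataFrame  # columns gene_a, gene_b, rule_applied

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_a"].duplicated().any() or t["gene_b"].duplicated().any():
            raise ValidationError("ortholog map is not one-to-one")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["gene_a"], self.table["gene_b"]))

    @property
    def genes_a(self) -> set[str]:
        return set(self.table["gene_a"])

    @property
    def genes_b(self) -> set[str]:
        return set(self.table["gene_b"])

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.table["gene_a"], self.table["gene_b"]))

    def __len__(self) -> int:
        return len(self.table)


def _validate_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANDIDATE_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValidationError(f"candidate table missing columns: {missing}")
    cand = candidates[CANDIDATE_COLUMNS].copy()
    if cand.empty:
        raise ValidationError("candidate table is empty")
    if (cand["weighted_score"] < 0).any():
        raise ValidationError("negative weighted scores")
    if cand.duplicated(["gene_a", "gene_b"]).any():
        raise ValidationError("duplicate (gene_a, gene_b) rows")
    if cand["best_score_reverse"].dtype == object:
        cand["best_score_reverse"] = (
            cand["best_score_reverse"].astype(str).str.lower().isin(["yes", "true", "1"])
        )
    cand["best_score_reverse"] = cand["best_score_reverse"].astype(bool)
    return cand


def _partner_rule(sorted_rows: list[dict]) -> str:
    """Which precedence level separated the chosen partner from the runner-up."""
    if len(sorted_rows) == 1:
        return RULE_UNIQUE
    top, second = sorted_rows[0], sorted_rows[1]
    if top["weighted_score"] > second["weighted_score"]:
        return RULE_SCORE
    if top["best_score_reverse"] and not second["best_score_reverse"]:
        return RULE_REVERSE
    return RULE_EXPRESSION


def resolve_orthologs(
    candidates: pd.DataFrame,
    expr_a: ExpressionSummary,
    expr_b: ExpressionSummary,
) -> OrthologMap:
    """Resolve a many-to-many candidate table into a one-to-one map.

    Deterministic and independent of input row order: all orderings use
    explicit keys down to lexicographic gene ids.
    """
    cand = _validate_candidates(candidates)

    # Per-A-gene candidate lists, best partner first.
    lists: dict[str, list[dict]] = {}
    for row in cand.itertuples(index=False):
        rec = {
            "gene_a": row.gene_a,
            "gene_b": row.gene_b,
            "weighted_score": float(row.weighted_score),
            "best_score_reverse": bool(row.best_score_reverse),
        }
        lists.setdefault(row.gene_a, []).append(rec)
    for a, rows in lists.items():
        rows.sort(
            key=lambda r: (
                -r["weighted_score"],
                not r["best_score_reverse"],
                -expr_b.mean(r["gene_b"]),
                -expr_b.frac(r["gene_b"]),
                r["gene_b"],
            )
        )

    # Initial per-gene rule before any collision fallback.
    base_rule = {a: _partner_rule(rows) for a, rows in lists.items()}
    fell_back: set[str] = set()

    while True:
        proposals: dict[str, list[str]] = {}
        for a, rows in lists.items():
            if rows:
                proposals.setdefault(rows[0]["gene_b"], []).append(a)
        collisions = {b: axs for b, axs in proposals.items() if len(axs) > 1}
        if not collisions:
            break
        for b, axs in collisions.items():
            axs.sort(
                key=lambda a: (
                    -lists[a][0]["weighted_score"],
                    not lists[a][0]["best_score_reverse"],
                    -expr_a.mean(a),
                    -expr_a.frac(a),
                    a,
                )
            )
            for loser in axs[1:]:
                lists[loser].pop(0)
                fell_back.add(loser)

    records = []
    for a in sorted(lists):
        rows = lists[a]
        if not rows:
            continue
        rule = RULE_GLOBAL if a in fell_back else base_rule[a]
        records.append((a, rows[0]["gene_b"], rule))
    table = pd.DataFrame(records, columns=["gene_a", "gene_b", "rule_applied"])
    return OrthologMap(table)


def expressed_orthologs(
    omap: OrthologMap,
    expr_a: ExpressionSummary,
    expr_b: ExpressionSummary,
    min_cells: int = 1,
) -> OrthologMap:
    """Keep pairs detected (>0 in >= min_cells cells) in both species."""
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    keep = [
        expr_a.n_expressing(a) >= min_cells and expr_b.n_expressing(b) >= min_cells
        for a, b in zip(omap.table["gene_a"], omap.table["gene_b"])
    ]
    return OrthologMap(omap.table.loc[keep].reset_index(drop=True))


def core_orthologs(maps: list[OrthologMap]) -> set[str]:
    """Species-A genes present in every map (conserved across all partners)."""
    if len(maps) < 2:
        raise ValidationError("need at least two maps")
    core = maps[0].genes_a
    for m in maps[1:]:
        core &= m.genes_a
    return core
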