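"""Per-library cell quality filters.

Rules fire in a fixed order per sequencing library: a hard UMI cap, a
UMI outlier rule at mean + k*SD (computed on cells surviving the cap;
sample SD, the R convention), a detected-gene floor, and a mitochondrial-fraction
ceiling. Each removed cell is attributed to the first rule that fires.
The 2SD rule is intentionally not idempotent: re-applying it to
survivors recomputes a tighter threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

RULES = ("umi_cap", "umi_outlier", "min_genes", "max_mito")


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_mito_fraction: float = 0.10
    umi_cap: int | None = None
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValidationError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")
        if self.umi_cap is not None and self.umi_cap <= 0:
            raise ValidationError("umi_cap must be positive")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be positive")


@dataclass
class QCResult:
    kept: list[str]
    removed_by_rule: dict[str, int]
    outlier_thresholds: dict[str, float]  # per library, mean + k*SD

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_rule.values())


def qc_records(
    matrix: ExpressionMatrix,
    mito_prefixes: tuple[str, ...] = ("mt:", "mt-", "MT-"),
    library: dict | None = None,
) -> pd.DataFrame:
    """Build a per-cell QC table (umi, genes, mito_frac, library) from counts."""
    if matrix.scale != "raw_counts":
        raise ValidationError("QC records need raw counts")
    umi = matrix.values.sum(axis=0)
    genes = (matrix.values > 0).sum(axis=0)
    is_mito = np.array([str(g).startswith(mito_prefixes) for g in matrix.genes])
    mito = matrix.values[is_mito, :].sum(axis=0) if is_mito.any() else np.zeros_like(umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito / np.where(umi > 0, umi, 1), 0.0)
    library = library or {}
    return pd.DataFrame(
        {
            "cell_id": list(matrix.cells),
            "umi": umi,
            "genes": genes,
            "mito_frac": mito_frac,
            "library": [library.get(c, "lib0") for c in matrix.cells],
        }
    )


def apply_qc(records: pd.DataFrame, thresholds: QCThresholds) -> QCResult:
    """Apply the four QC rules per library; return survivors and rule counts.

    ``records`` columns: cell_id, umi, genes, mito_frac and optionally
    library (one global library assumed when absent).
    """
    req = {"cell_id", "umi", "genes", "mito_frac"}
    if not req.issubset(records.columns):
        raise ValidationError(f"QC table needs columns {sorted(req)}")
    if records.empty:
        raise ValidationError("empty QC record table")
    rec = records.copy()
    if "library" not in rec.columns:
        rec["library"] = "lib0"
    if not rec["mito_frac"].between(0, 1).all():
        raise ValidationError("mito_frac outside [0, 1]")

    counts = {r: 0 for r in RULES}
    kept: list[str] = []
    outlier_thr: dict[str, float] = {}
    for lib, sub in rec.groupby("library", sort=True):
        alive = sub
        # rule 1: hard UMI cap
        if thresholds.umi_cap is not None:
            capped = alive["umi"] > thresholds.umi_cap
            counts["umi_cap"] += int(capped.sum())
            alive = alive.loc[~capped]
        # rule 2: mean + k*SD outliers on cells surviving the cap
        if len(alive) >= 2:
            mu = float(alive["umi"].mean())
            sd = float(alive["umi"].std(ddof=1))
            thr = mu + thresholds.sd_multiplier * sd
            outlier_thr[str(lib)] = thr
            out = alive["umi"] > thr
            counts["umi_outlier"] += int(out.sum())
            alive = alive.loc[~out]
        elif len(alive) == 1:
            logger.warning("library %s has a single cell; UMI outlier rule skipped", lib)
        # rule 3: detected-gene floor
        low = alive["genes"] < thresholds.min_genes
        counts["min_genes"] += int(low.sum())
        alive = alive.loc[~low]
        # rule 4: mitochondrial ceiling
        hi = alive["mito_frac"] > thresholds.max_mito_fraction
        counts["max_mito"] += int(hi.sum())
        alive = alive.loc[~hi]
        kept.extend(alive["cell_id"].tolist())

    return QCResult(kept=kept, removed_by_rule=counts, outlier_thresholds=outlier_thr)
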