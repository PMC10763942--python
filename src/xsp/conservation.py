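"""Fuse unsupervised AUROC and supervised enrichment into a conservation map.

The conservation score of a cell-type pair is the arithmetic mean of
its neighbor-voting AUROC and its scaled enrichment score; pairs scored
by only one arm carry that value alone and are flagged partial. A pair
is retained when it is a reciprocal best hit or its conservation score
is strictly greater than the retention threshold (default 0.80).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ScoreMatrix, ValidationError

COLUMNS = [
    "type_a",
    "type_b",
    "auroc",
    "enrichment",
    "score",
    "reciprocal",
    "partial",
    "retained",
]


def fuse(
    auroc: ScoreMatrix,
    enrichment: ScoreMatrix,
    reciprocal_pairs: set[tuple[str, str]] | None = None,
    threshold: float = 0.80,
    label_map: dict | None = None,
) -> pd.DataFrame:
    """Combine the two score matrices into a long-format conservation map.

    ``label_map`` renames enrichment labels onto the AUROC label space;
    unknown keys are an error listing the orphans.
    """
    a = auroc.data
    e = enrichment.data.copy()
    if label_map:
        orphans = [k for k in label_map if k not in e.index and k not in e.columns]
        if orphans:
            raise ValidationError(f"label map entries match nothing: {orphans}")
        e = e.rename(index=label_map, columns=label_map)
    reciprocal_pairs = reciprocal_pairs or set()

    rows = sorted(set(a.index) | set(e.index))
    cols = sorted(set(a.columns) | set(e.columns))
    records = []
    for ta in rows:
        for tb in cols:
            va = a.at[ta, tb] if (ta in a.index and tb in a.columns) else np.nan
            ve = e.at[ta, tb] if (ta in e.index and tb in e.columns) else np.nan
            present = [v for v in (va, ve) if not np.isnan(v)]
            if not present:
                continue
            score = float(np.mean(present))
            recip = (ta, tb) in reciprocal_pairs
            records.append(
                {
                    "type_a": ta,
                    "type_b": tb,
                    "auroc": va,
                    "enrichment": ve,
                    "score": score,
                    "reciprocal": recip,
                    "partial": len(present) == 1,
                    "retained": recip or score > threshold,
                }
            )
    return pd.DataFrame(records, columns=COLUMNS)


def render_map(
    cons: pd.DataFrame,
    species_a: str = "A",
    species_b: str = "B",
    figure_path: str | None = None,
) -> pd.DataFrame:
    """Long-format table of retained pairs, ordered by species then score.

    Optionally writes a heatmap of retained conservation scores.
    """
    if cons.empty:
        raise ValidationError("empty conservation map")
    retained = cons[cons["retained"]].copy()
    if retained.empty:
        warnings.warn("no retained cell-type pairs")
    retained.insert(0, "species_a", species_a)
    retained.insert(2, "species_b", species_b)
    retained = retained.sort_values(
        ["species_a", "score", "type_a", "type_b"], ascending=[True, False, True, True]
    ).reset_index(drop=True)
    if figure_path is not None and not retained.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = retained.pivot_table(index="type_a", columns="type_b", values="score")
        fig, ax = plt.subplots(figsize=(1 + 0.5 * grid.shape[1], 1 + 0.5 * grid.shape[0]))
        im = ax.imshow(grid.to_numpy(), cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90)
        ax.set_yticks(range(grid.shape[0]), grid.index)
        ax.set_xlabel(species_b)
        ax.set_ylabel(species_a)
        fig.colorbar(im, ax=ax, label="conservation score")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return retained


def truth_metrics(
    cons: pd.DataFrame, planted_pairs: set[tuple[str, str]]
) -> dict[str, float]:
    """Precision/recall of retained pairs against a planted homology set."""
    retained = {
        (r.type_a, r.type_b) for r in cons.itertuples(index=False) if r.retained
    }
    tp = len(retained & planted_pairs)
    if not retained:
        return {"precision": 0.0, "recall": 0.0, "empty_retained": True,
                "n_retained": 0, "n_planted": len(planted_pairs)}
    recall = tp / len(planted_pairs) if planted_pairs else 0.0
    return {
        "precision": tp / len(retained),
        "recall": recall,
        "empty_retained": False,
        "n_retained": len(retained),
        "n_planted": len(planted_pairs),
    }
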