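"""Marker discovery, ortholog translation and gene-set enrichment scoring.

Markers are found one-vs-rest with a two-sided Wilcoxon rank-sum test
(Bonferroni-adjusted), kept when up-regulated in the focal type,
detected in at least ``min_pct`` of its cells and adjusted p <= alpha;
genes claimed by more than one cell type are then discarded, since in
continuously differentiating tissue such shared genes mark states, not
types. Translated marker sets are scored on the other species'
pseudo-bulk profiles with a rank-based gene-set variation statistic:

1. per gene, a Gaussian-kernel cumulative density across samples
   (bandwidth = per-gene SD / 4);
2. per sample, genes ordered by that statistic and given symmetric rank
   scores |p/2 - rank|;
3. a weighted Kolmogorov-Smirnov random walk (weight exponent 1) over
   the ordered genes;
4. enrichment score = maximum positive deviation + maximum negative
   deviation of the walk (signed sum), so raw scores lie in [-1, 1].

The raw set x profile matrix is finally min-max scaled to [0, 1]
globally, preserving between-set comparability for the fusion step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, PseudoProfileMatrix, ScoreMatrix, ValidationError
from .orthologs import OrthologMap


@dataclass
class MarkerCatalog:
    """Per cell type, signature genes surviving the discovery filters."""

    sets: dict[str, pd.DataFrame]  # type -> columns gene, effect, p_adj, pct_expressing
    translation_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def genes(self, cell_type: str) -> list[str]:
        return self.sets[cell_type]["gene"].tolist()

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.sets)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t in self.cell_types:
            f = self.sets[t].copy()
            f.insert(0, "cell_type", t)
            frames.append(f)
        if not frames:
            return pd.DataFrame(
                columns=["cell_type", "gene", "effect", "p_adj", "pct_expressing"]
            )
        return pd.concat(frames, ignore_index=True)


def find_markers(
    matrix: ExpressionMatrix,
    labels: dict,
    min_pct: float = 0.25,
    alpha: float = 0.05,
) -> MarkerCatalog:
    """One-vs-rest rank-sum markers per cell type, multi-type genes dropped."""
    if matrix.scale != "lognorm":
        raise ValidationError("marker discovery expects lognorm expression")
    missing = [c for c in matrix.cells if c not in labels]
    if missing:
        raise ValidationError(f"unlabeled cells: {missing[:10]}")
    lab = np.array([labels[c] for c in matrix.cells])
    types = sorted(set(lab))
    if len(types) < 2:
        raise ValidationError("need at least 2 cell types")
    n_genes = matrix.n_genes
    vals = matrix.values

    raw_sets: dict[str, pd.DataFrame] = {}
    for t in types:
        focal = lab == t
        if focal.sum() < 3:
            warnings.warn(f"cell type {t!r} has < 3 cells; excluded from marker search")
            continue
        x = vals[:, focal]
        y = vals[:, ~focal]
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                x, y, axis=1, alternative="two-sided", method="asymptotic"
            )
        pvals = np.asarray(res.pvalue)
        # ties everywhere (gene all-zero) yield NaN p under the tie-corrected
        # normal approximation; such genes carry no signal
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        p_adj = np.minimum(pvals * n_genes, 1.0)  # Bonferroni
        effect = x.mean(axis=1) - y.mean(axis=1)
        pct = (x > 0).mean(axis=1)
        keep = (effect > 0) & (pct >= min_pct) & (p_adj <= alpha)
        sub = pd.DataFrame(
            {
                "gene": matrix.genes[keep],
                "effect": effect[keep],
                "p_adj": p_adj[keep],
                "pct_expressing": pct[keep],
            }
        ).sort_values(["p_adj", "gene"], ascending=[True, True], key=None)
        sub = sub.reset_index(drop=True)
        raw_sets[t] = sub

    # multi-type exclusion: a signature gene must identify a single type
    claimed: dict[str, int] = {}
    for t, sub in raw_sets.items():
        for g in sub["gene"]:
            claimed[g] = claimed.get(g, 0) + 1
    sets = {
        t: sub.loc[[claimed[g] == 1 for g in sub["gene"]]].reset_index(drop=True)
        for t, sub in raw_sets.items()
    }
    return MarkerCatalog(sets=sets)


def translate_markers(catalog: MarkerCatalog, omap: OrthologMap) -> MarkerCatalog:
    """Map marker genes through a one-to-one ortholog map; track set sizes."""
    a2b = omap.a_to_b()
    sets: dict[str, pd.DataFrame] = {}
    sizes: dict[str, tuple[int, int]] = {}
    for t, sub in catalog.sets.items():
        keep = sub["gene"].isin(a2b)
        out = sub.loc[keep].copy()
        out["gene"] = out["gene"].map(a2b)
        sets[t] = out.reset_index(drop=True)
        sizes[t] = (len(sub), len(out))
        if len(out) == 0 and len(sub) > 0:
            warnings.warn(f"marker set {t!r} empty after ortholog translation")
    return MarkerCatalog(sets=sets, translation_sizes=sizes)


def _kernel_cdf(vals: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate per gene across samples (bandwidth sd/4)."""
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    h = sd / 4.0
    diff = (vals[:, :, None] - vals[:, None, :]) / h[:, :, None]  # (g, sample_j, obs_k)
    return stats.norm.cdf(diff).mean(axis=2)


def gsva_scores(
    profiles: PseudoProfileMatrix,
    catalog: MarkerCatalog,
    min_set_size: int = 5,
    scale: bool = True,
) -> ScoreMatrix:
    """Gene-set variation scores of each marker set in each profile."""
    if profiles.n_profiles < 3:
        raise ValidationError("need at least 3 profiles (samples)")
    vals = profiles.values
    genes = np.asarray(profiles.genes)

    const = vals.std(axis=1, ddof=1) == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant gene(s) dropped (kernel SD = 0)")
        vals = vals[~const]
        genes = genes[~const]
    p = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable: dict[str, np.ndarray] = {}
    for t in catalog.cell_types:
        members = np.array(
            [gene_pos[g] for g in catalog.genes(t) if g in gene_pos], dtype=int
        )
        if len(members) < min_set_size:
            warnings.warn(
                f"marker set {t!r} has {len(members)} usable genes (< {min_set_size}); dropped"
            )
            continue
        usable[t] = members
    if not usable:
        raise ValidationError("no marker set is large enough to score")

    z = _kernel_cdf(vals)  # (genes, samples)
    n_samples = z.shape[1]
    raw = pd.DataFrame(
        np.nan, index=sorted(usable), columns=profiles.profiles, dtype=float
    )
    order = np.argsort(-z, axis=0, kind="stable")  # genes by decreasing statistic
    ranks = np.empty_like(order)
    for j in range(n_samples):
        ranks[order[:, j], j] = np.arange(1, p + 1)
    sym = np.abs(p / 2.0 - ranks)  # symmetric rank scores

    for t, members in usable.items():
        in_set = np.zeros(p, dtype=bool)
        in_set[members] = True
        m = int(in_set.sum())
        for j in range(n_samples):
            ordered_in = in_set[order[:, j]]
            w = sym[order[:, j], j] * ordered_in
            denom = w.sum()
            pos = np.cumsum(w) / denom
            neg = np.cumsum(~ordered_in) / (p - m)
            walk = pos - neg
            es = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            raw.iloc[raw.index.get_loc(t), j] = es

    ds = profiles.meta["dataset"].iloc[0] if len(profiles.meta) else "B"
    if not scale:
        return ScoreMatrix(raw, "marker_sets", ds, "enrichment")
    lo, hi = np.nanmin(raw.to_numpy()), np.nanmax(raw.to_numpy())
    if hi == lo:
        warnings.warn("degenerate enrichment matrix (all scores equal); scaled to 0.5")
        scaled = raw * 0.0 + 0.5
    else:
        scaled = (raw - lo) / (hi - lo)
    return ScoreMatrix(scaled, "marker_sets", ds, "enrichment")
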