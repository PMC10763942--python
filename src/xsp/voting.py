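"""Unsupervised cross-dataset cell-type matching by neighbor voting.

Pseudo-cell profiles from two datasets are merged over shared ortholog
genes; a Spearman similarity network is built and each column converted
to scaled midranks (rank / N, in (0, 1]). For every cell type of one
dataset, profiles of the other dataset receive degree-normalized votes
from that type's profiles, and the AUROC of those votes against the
true type membership scores how replicable the type is across datasets.
AUROC is computed with the Mann-Whitney midrank formula

    AUROC = (R+ - P(P+1)/2) / (P * N)

with R+ the midrank sum of the positive (same-type) test profiles, P
their count and N the count of the remaining test profiles. Both
train/test orientations are computed and averaged. Confident matches
are thresholded top hits; a pair is a reciprocal best hit when each
type is the other's best-scoring match.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import PseudoProfileMatrix, ScoreMatrix, ValidationError


def variable_genes(
    matrices: list[PseudoProfileMatrix],
    n_bins: int = 10,
    top_quantile: float = 0.75,
    min_genes: int = 10,
) -> list[str]:
    """Select highly variable genes shared by all datasets.

    Per dataset, genes are binned into deciles of median expression and
    the top-variance quartile of each bin is kept; the final list is the
    intersection across datasets. Constant genes are never selected.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two datasets")
    selected: list[set] = []
    for m in matrices:
        if m.n_profiles < 3:
            raise ValidationError("need at least 3 profiles per dataset")
        med = np.median(m.values, axis=1)
        var = m.values.var(axis=1, ddof=0)
        edges = np.quantile(med, np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(edges, med, side="right") - 1, 0, n_bins - 1)
        keep = np.zeros(m.values.shape[0], dtype=bool)
        for b in np.unique(bins):
            mask = bins == b
            cut = np.quantile(var[mask], top_quantile)
            keep[mask] = (var[mask] >= cut) & (var[mask] > 0)
        selected.append({g for g, k in zip(m.genes, keep) if k})
    shared = set.intersection(*selected)
    genes = sorted(shared)
    if len(genes) < min_genes:
        raise ValidationError(
            f"only {len(genes)} variable genes shared across datasets (< {min_genes})"
        )
    return genes


def merge_profiles(
    a: PseudoProfileMatrix, b: PseudoProfileMatrix, genes: list
) -> PseudoProfileMatrix:
    """Column-concatenate two datasets' profiles over a shared gene list."""
    sa, sb = a.subset_genes(genes), b.subset_genes(genes)
    values = np.column_stack([sa.values, sb.values])
    profiles = pd.Index(list(sa.profiles) + list(sb.profiles))
    meta = pd.concat([sa.meta, sb.meta])
    return PseudoProfileMatrix(values, pd.Index(genes), profiles, a.kind, meta)


def voting_network(profiles: PseudoProfileMatrix) -> pd.DataFrame:
    """Spearman similarity, columns converted to scaled midranks in (0, 1]."""
    vals = profiles.values
    if vals.std(axis=0).min() == 0:
        bad = profiles.profiles[vals.std(axis=0) == 0][0]
        raise ValidationError(f"constant profile: {bad}")
    ranks = stats.rankdata(vals, axis=0)
    z = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
    corr = z.T @ z / vals.shape[0]
    n = corr.shape[0]
    net = stats.rankdata(corr, axis=0) / n  # per-column scaled midranks
    return pd.DataFrame(net, index=profiles.profiles, columns=profiles.profiles)


def _auroc_from_votes(votes: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUROC of votes for the positive mask (midrank ties)."""
    ranks = stats.rankdata(votes)
    p = int(positive.sum())
    n = len(votes) - p
    if p == 0 or n == 0:
        return np.nan
    r_pos = ranks[positive].sum()
    return float((r_pos - p * (p + 1) / 2) / (p * n))


def _one_orientation(
    net: pd.DataFrame, meta: pd.DataFrame, train_ds: str, test_ds: str
) -> pd.DataFrame:
    train_mask = (meta["dataset"] == train_ds).to_numpy()
    test_mask = (meta["dataset"] == test_ds).to_numpy()
    w = net.to_numpy()
    types_train = sorted(meta.loc[train_mask, "cell_type"].unique())
    types_test = sorted(meta.loc[test_mask, "cell_type"].unique())
    test_types_per_profile = meta.loc[test_mask, "cell_type"].to_numpy()
    denom = w[np.ix_(train_mask, test_mask)].sum(axis=0)  # network mass per test profile
    out = pd.DataFrame(np.nan, index=types_train, columns=types_test, dtype=float)
    for t in types_train:
        members = train_mask & (meta["cell_type"] == t).to_numpy()
        votes = w[np.ix_(members, test_mask)].sum(axis=0) / denom
        for s in types_test:
            positive = test_types_per_profile == s
            if positive.sum() < 2:
                continue  # AUROC recorded as missing for tiny test types
            out.at[t, s] = _auroc_from_votes(votes, positive)
    return out


def auroc_matrix(net: pd.DataFrame, meta: pd.DataFrame) -> ScoreMatrix:
    """Cross-dataset cell-type AUROC matrix, mean of both orientations.

    ``meta`` indexes the network's profiles with columns ``dataset`` and
    ``cell_type``; exactly two datasets are required.
    """
    if not meta.index.equals(net.index):
        raise ValidationError("meta must index the network profiles")
    datasets = sorted(meta["dataset"].unique())
    if len(datasets) != 2:
        raise ValidationError(f"exactly 2 datasets required, got {datasets}")
    d1, d2 = datasets
    fwd = _one_orientation(net, meta, d1, d2)  # rows: d1 types, cols: d2 types
    rev = _one_orientation(net, meta, d2, d1).T  # transposed to same shape
    rows = sorted(set(fwd.index) | set(rev.index))
    cols = sorted(set(fwd.columns) | set(rev.columns))
    fwd = fwd.reindex(index=rows, columns=cols)
    rev = rev.reindex(index=rows, columns=cols)
    stacked = np.stack([fwd.to_numpy(), rev.to_numpy()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)  # single-orientation values carried alone
    return ScoreMatrix(pd.DataFrame(mean, index=rows, columns=cols), d1, d2, "auroc")


@dataclass
class HitList:
    """Thresholded best matches with reciprocal-best-hit flags."""

    records: pd.DataFrame  # columns train_type, test_type, auroc, reciprocal
    threshold: float

    @property
    def reciprocal_pairs(self) -> set[tuple[str, str]]:
        """Reciprocal pairs as (row-dataset type, column-dataset type)."""
        rec = self.records[self.records["reciprocal"]]
        pairs = set()
        for r in rec.itertuples(index=False):
            if r.orientation == "row->col":
                pairs.add((r.train_type, r.test_type))
            else:
                pairs.add((r.test_type, r.train_type))
        return pairs


def top_hits(matrix: ScoreMatrix, threshold: float = 0.80) -> HitList:
    """Best hit per cell type with AUROC >= threshold, both orientations."""
    if not 0.5 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0.5, 1]")
    df = matrix.data
    best_col: dict[str, tuple[str, float]] = {}
    for r in df.index:
        row = df.loc[r].dropna()
        if row.empty:
            continue
        c = row.idxmax()
        best_col[r] = (c, float(row[c]))
    best_row: dict[str, tuple[str, float]] = {}
    for c in df.columns:
        col = df[c].dropna()
        if col.empty:
            continue
        r = col.idxmax()
        best_row[c] = (r, float(col[r]))

    records = []
    for r, (c, v) in sorted(best_col.items()):
        if v >= threshold:
            recip = best_row.get(c, (None,))[0] == r and best_row[c][1] >= threshold
            records.append((r, c, v, recip, "row->col"))
    for c, (r, v) in sorted(best_row.items()):
        if v >= threshold:
            recip = best_col.get(r, (None,))[0] == c and best_col[r][1] >= threshold
            records.append((c, r, v, recip, "col->row"))
    rec = pd.DataFrame(
        records, columns=["train_type", "test_type", "auroc", "reciprocal", "orientation"]
    ).sort_values(["auroc", "train_type"], ascending=[False, True]).reset_index(drop=True)
    return HitList(records=rec, threshold=threshold)
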