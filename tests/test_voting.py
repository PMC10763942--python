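"""Neighbor-voting: variable genes, network, AUROC formula, top hits."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xsp import (
    PseudoProfileMatrix,
    ScoreMatrix,
    ValidationError,
    auroc_matrix,
    merge_profiles,
    top_hits,
    variable_genes,
    voting_network,
)


def profiles(vals, ds, types=None):
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[1]
    types = types or [f"t{j}" for j in range(n)]
    ids = pd.Index([f"{ds}|{types[j]}|{j}" for j in range(n)])
    meta = pd.DataFrame(
        {"cell_type": types, "dataset": ds,
         "members": [(f"{ds}c{j}",) for j in range(n)]},
        index=ids,
    )
    return PseudoProfileMatrix(
        vals, pd.Index([f"g{i}" for i in range(vals.shape[0])]), ids,
        "pseudo_cell", meta
    )


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def variable_genes_oracle(mats, n_bins=10):
    """Literal per-dataset recipe, re-coded with plain loops."""
    per_ds = []
    for m in mats:
        med = [float(np.median(m.values[i])) for i in range(m.values.shape[0])]
        var = [float(np.var(m.values[i])) for i in range(m.values.shape[0])]
        qs = np.quantile(med, np.linspace(0, 1, n_bins + 1))
        chosen = set()
        for b in range(n_bins):
            idx = [
                i for i, v in enumerate(med)
                if (np.searchsorted(qs, v, side="right") - 1 == b)
                or (b == n_bins - 1 and np.searchsorted(qs, v, side="right") - 1 >= n_bins)
            ]
            if not idx:
                continue
            cut = np.quantile([var[i] for i in idx], 0.75)
            chosen |= {m.genes[i] for i in idx if var[i] >= cut and var[i] > 0}
        per_ds.append(chosen)
    return sorted(set.intersection(*per_ds))


class TestVariableGenes:
    def test_extreme_variance_gene_selected(self, rng):
        va = rng.uniform(1, 2, size=(40, 6))
        vb = rng.uniform(1, 2, size=(40, 6))
        va[0] = [0, 50, 0, 50, 0, 50]
        vb[0] = [0, 60, 0, 60, 0, 60]
        # pad obvious variable genes so the shared list clears the minimum
        for i in range(1, 12):
            va[i] *= rng.uniform(0.1, 5, 6)
            vb[i] *= rng.uniform(0.1, 5, 6)
        hvg = variable_genes(
            [profiles(va, "A"), profiles(vb, "B")], min_genes=1
        )
        assert "g0" in hvg

    def test_constant_gene_never_selected(self, rng):
        va = rng.uniform(1, 2, size=(40, 6))
        vb = rng.uniform(1, 2, size=(40, 6))
        va[3] = 1.0  # constant in A only
        hvg = variable_genes([profiles(va, "A"), profiles(vb, "B")], min_genes=1)
        assert "g3" not in hvg

    def test_matches_recipe_oracle(self, rng):
        mats = [
            profiles(rng.lognormal(0, 1, size=(200, 8)), "A"),
            profiles(rng.lognormal(0, 1, size=(200, 8)), "B"),
        ]
        assert variable_genes(mats, min_genes=1) == variable_genes_oracle(mats)

    def test_too_few_shared_genes_error(self, rng):
        va = rng.uniform(1, 2, size=(12, 4))
        with pytest.raises(ValidationError):
            variable_genes([profiles(va, "A"), profiles(va * 0 + 1, "B")])


# ---------------------------------------------------------------------------
# voting network
# ---------------------------------------------------------------------------

class TestVotingNetwork:
    def test_identical_profiles_have_maximal_mutual_rank(self, rng):
        v = rng.uniform(0, 5, size=(20, 4))
        v[:, 1] = v[:, 0]
        net = voting_network(profiles(v, "A"))
        n = net.shape[0]
        assert net.iloc[0, 1] == net.iloc[:, 1].max()

    def test_columns_are_scaled_midranks(self, rng):
        v = rng.normal(size=(30, 5))
        v = v - v.min() + 0.1
        net = voting_network(profiles(v, "A")).to_numpy()
        n = net.shape[0]
        for j in range(n):
            assert sorted(net[:, j]) == pytest.approx(
                [(k + 1) / n for k in range(n)]
            )

    def test_matches_definitional_oracle(self, rng):
        v = rng.poisson(6, size=(25, 6)).astype(float)
        net = voting_network(profiles(v, "A")).to_numpy()
        n = 6
        corr = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                corr[i, j] = stats.spearmanr(v[:, i], v[:, j]).statistic
        expected = stats.rankdata(corr, axis=0) / n
        assert np.allclose(net, expected, atol=1e-12)

    def test_constant_profile_named_in_error(self, rng):
        v = rng.uniform(1, 2, size=(10, 3))
        v[:, 2] = 1.0
        with pytest.raises(ValidationError, match="t2"):
            voting_network(profiles(v, "A"))


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc_bruteforce(votes, positive):
    """Concordant-pair counting with ties worth 0.5."""
    pos = votes[positive]
    neg = votes[~positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_rank_formula_equals_pair_counting():
    from xsp.voting import _auroc_from_votes

    rng = np.random.default_rng(77)
    for _ in range(25):
        votes = rng.integers(0, 15, size=40).astype(float)  # heavy ties
        positive = rng.random(40) < 0.3
        if positive.sum() in (0, 40):
            continue
        assert _auroc_from_votes(votes, positive) == pytest.approx(
            auroc_bruteforce(votes, positive), abs=1e-12
        )


def block_instance(rng, noise=0.0):
    """Two datasets, two types each, block-identical expression for matches."""
    g = 30
    base1, base2 = rng.uniform(1, 5, g), rng.uniform(1, 5, g)
    cols, types, ds = [], [], []
    for d in ("A", "B"):
        for t, base in (("x", base1), ("y", base2)):
            for _ in range(4):
                cols.append(base + rng.normal(0, noise, g) if noise else base.copy())
                types.append(t)
                ds.append(d)
    vals = np.abs(np.column_stack(cols))
    ids = pd.Index([f"{ds[j]}|{types[j]}|{j}" for j in range(len(cols))])
    meta = pd.DataFrame(
        {"cell_type": types, "dataset": ds,
         "members": [(f"c{j}",) for j in range(len(cols))]},
        index=ids,
    )
    return PseudoProfileMatrix(
        vals, pd.Index([f"g{i}" for i in range(g)]), ids, "pseudo_cell", meta
    )


class TestAurocMatrix:
    def test_block_identical_types_get_auroc_one(self, rng):
        prof = block_instance(rng, noise=0.05)
        net = voting_network(prof)
        sm = auroc_matrix(net, prof.meta[["dataset", "cell_type"]])
        assert sm.data.at["x", "x"] == pytest.approx(1.0)
        assert sm.data.at["y", "y"] == pytest.approx(1.0)
        assert sm.data.at["x", "y"] == pytest.approx(0.0)

    def test_uninformative_votes_give_half(self):
        from xsp.voting import _auroc_from_votes

        votes = np.full(10, 3.0)
        positive = np.array([True] * 4 + [False] * 6)
        assert _auroc_from_votes(votes, positive) == pytest.approx(0.5)

    def test_random_instance_votes_match_bruteforce(self, rng):
        # full pipeline AUROC vs brute force recomputed from the vote vectors
        g, per = 25, 5
        types = ["x", "y", "z", "w"]
        cols, tys, ds = [], [], []
        for d in ("A", "B"):
            for t in types:
                base = rng.uniform(1, 5, g)
                for _ in range(per):
                    cols.append(base + rng.normal(0, 0.5, g))
                    tys.append(t)
                    ds.append(d)
        vals = np.abs(np.column_stack(cols))
        ids = pd.Index([f"{ds[j]}|{tys[j]}|{j}" for j in range(len(cols))])
        meta = pd.DataFrame(
            {"cell_type": tys, "dataset": ds,
             "members": [(f"c{j}",) for j in range(len(cols))]}, index=ids)
        prof = PseudoProfileMatrix(
            vals, pd.Index([f"g{i}" for i in range(g)]), ids, "pseudo_cell", meta)
        net = voting_network(prof)
        sm = auroc_matrix(net, prof.meta[["dataset", "cell_type"]])

        # brute-force one orientation, then average with the transpose
        w = net.to_numpy()
        m = prof.meta
        expect = {}
        for train_ds, test_ds in (("A", "B"), ("B", "A")):
            tr = (m["dataset"] == train_ds).to_numpy()
            te = (m["dataset"] == test_ds).to_numpy()
            denom = w[np.ix_(tr, te)].sum(axis=0)
            for t in types:
                votes = w[np.ix_(tr & (m["cell_type"] == t).to_numpy(), te)].sum(0) / denom
                for s in types:
                    positive = m.loc[te, "cell_type"].to_numpy() == s
                    expect[(train_ds, t, s)] = auroc_bruteforce(votes, positive)
        for t in types:
            for s in types:
                avg = (expect[("A", t, s)] + expect[("B", s, t)]) / 2
                assert sm.data.at[t, s] == pytest.approx(avg, abs=1e-12)

    def test_requires_two_datasets(self, rng):
        prof = profiles(rng.uniform(1, 2, size=(10, 4)), "A")
        net = voting_network(prof)
        with pytest.raises(ValidationError):
            auroc_matrix(net, prof.meta[["dataset", "cell_type"]])


# ---------------------------------------------------------------------------
# top hits / reciprocal best hits
# ---------------------------------------------------------------------------

def hits_oracle(df, thr):
    """Brute-force argmax + RBH on a score DataFrame."""
    best_row = {r: df.loc[r].idxmax() for r in df.index}
    best_col = {c: df[c].idxmax() for c in df.columns}
    out = set()
    for r, c in best_row.items():
        if df.at[r, c] >= thr:
            recip = best_col[c] == r and df.at[best_col[c], c] >= thr
            out.add((r, c, "row->col", recip))
    for c, r in best_col.items():
        if df.at[r, c] >= thr:
            recip = best_row[r] == c and df.at[r, best_row[r]] >= thr
            out.add((c, r, "col->row", recip))
    return out


class TestTopHits:
    def matrix(self, arr, rows, cols):
        return ScoreMatrix(pd.DataFrame(arr, index=rows, columns=cols), "A", "B")

    def test_unique_maxima_are_reciprocal(self):
        sm = self.matrix([[0.95, 0.6], [0.55, 0.9]], ["x", "y"], ["u", "v"])
        h = top_hits(sm, 0.8)
        assert h.reciprocal_pairs == {("x", "u"), ("y", "v")}
        assert h.records["reciprocal"].all()

    def test_threshold_boundary_inclusive(self):
        for v, included in ((0.74, False), (0.75, True), (0.76, True)):
            sm = self.matrix([[v]], ["x"], ["u"])
            h = top_hits(sm, 0.75)
            assert (len(h.records) > 0) is included

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            arr = rng.uniform(0.4, 1.0, size=(5, 4))
            sm = self.matrix(arr, list("abcde"), list("uvwx"))
            h = top_hits(sm, 0.8)
            got = {
                (r.train_type, r.test_type, r.orientation, r.reciprocal)
                for r in h.records.itertuples(index=False)
            }
            assert got == hits_oracle(sm.data, 0.8)

    def test_reciprocity_is_symmetric(self, rng):
        arr = rng.uniform(0.5, 1.0, size=(6, 6))
        h = top_hits(self.matrix(arr, list("abcdef"), list("uvwxyz")), 0.75)
        rec = h.records
        fwd = {(r.train_type, r.test_type) for r in rec[rec.reciprocal].itertuples()
               if r.orientation == "row->col"}
        bwd = {(r.test_type, r.train_type) for r in rec[rec.reciprocal].itertuples()
               if r.orientation == "col->row"}
        assert fwd == bwd

    def test_invalid_threshold(self):
        sm = self.matrix([[0.9]], ["x"], ["u"])
        for thr in (0.5, 1.2):
            with pytest.raises(ValidationError):
                top_hits(sm, thr)


def test_merge_profiles_concatenates_datasets(rng):
    a = profiles(rng.uniform(1, 2, size=(10, 3)), "A")
    b = profiles(rng.uniform(1, 2, size=(10, 4)), "B")
    merged = merge_profiles(a, b, [f"g{i}" for i in range(10)])
    assert merged.n_profiles == 7
    assert merged.meta["dataset"].tolist() == ["A"] * 3 + ["B"] * 4
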