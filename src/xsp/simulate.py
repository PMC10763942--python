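"""Two-species synthetic single-cell data with planted cell-type homology.

The generator emulates the statistical structure the cross-species
analysis assumes: two species whose cell types share latent expression
programs through a (noisy, many-to-many) ortholog candidate table.

Structure of the default configuration:

* ``n_matched`` cell-type pairs share identical programs through the
  true ortholog map; types 0 and 1 form a progenitor -> differentiated
  continuum (the progenitor expresses half of the differentiated type's
  markers at intermediate level, mirrored in both species).
* One species-specific type per species carries its own ortholog-block
  markers (plus private-gene markers), down-regulates a dedicated,
  per-species block of the matched marker genes, and mildly tilts toward
  one matched program (a sub-threshold elevation, different program per
  species). The down-only signature keeps the species-specific types
  from being flat in variable-gene space (two flat residual types would
  become each other's best hit by elimination), never mimics the
  up-regulated matched programs, and the disjoint down blocks plus the
  divergent tilts keep the two unique types mutually dissimilar, so the
  unique type's best cross-species hit is always a matched type that
  itself reciprocates with its true partner.
* Counts are negative binomial over per-cell log-normal depth factors
  with per-library depth multipliers; dispersion 0 falls back to
  Poisson.
* The candidate table contains every true ortholog pair with the top
  weighted score and best-score-reverse set, plus decoy candidates at
  lower (or, with small probability, tied) scores, exercising all three
  resolution rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError
from .orthologs import OrthologMap


@dataclass(frozen=True)
class SimConfig:
    n_matched: int = 5                  # homologous type pairs (incl. the continuum pair)
    n_orthologs: int = 3000             # true one-to-one ortholog pairs
    n_private_genes: int = 200          # species-specific genes per species
    n_markers_per_type: int = 40
    marker_log2fc: float = 2.0          # 4-fold elevation of a type's markers
    continuum_frac: float = 0.5         # fraction of differentiated markers bled into the progenitor
    cells_per_type: int = 300
    nb_dispersion: float = 0.15         # NB alpha; 0 -> Poisson
    baseline_mean: float = 2.0          # scale of per-gene baseline expression
    libraries_per_species: int = 2
    library_depth_range: tuple[float, float] = (1.0, 1.6)
    depth_log_sigma: float = 0.3        # per-cell log-normal depth spread
    decoy_fraction: float = 0.3         # fraction of A genes with decoy candidates
    decoy_tie_prob: float = 0.1         # decoy score ties the true pair's score
    unique_down_fraction: float = 0.4   # matched marker genes down-regulated per unique type
    unique_down_log2_range: tuple[float, float] = (1.0, 3.0)  # 1/2x .. 1/8x
    unique_tilt_ratio: float = 0.25     # tilt effect as a fraction of marker_log2fc
    unique_tilt_fraction: float = 0.5   # fraction of that program's markers tilted
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_matched, self.n_orthologs, self.n_markers_per_type,
               self.cells_per_type, self.libraries_per_species) < 1:
            raise ValidationError("all counts must be positive")
        if self.marker_log2fc <= 0:
            raise ValidationError("marker effect must be positive")
        needed = (self.n_matched + 2) * self.n_markers_per_type
        if needed > self.n_orthologs:
            raise ValidationError(
                f"{needed} marker positions exceed {self.n_orthologs} orthologs"
            )

    @property
    def matched_types(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_matched)]

    def types(self, species: str) -> list[str]:
        return self.matched_types + [f"unique{species}"]


@dataclass
class SyntheticTruth:
    planted_pairs: set[tuple[str, str]]
    markers: dict[str, dict[str, list[str]]]      # species -> type -> genes
    ortholog_map: OrthologMap
    expected_mean: dict[str, pd.DataFrame]        # species -> genes x types


@dataclass
class SimResult:
    expr_a: ExpressionMatrix
    labels_a: dict
    libraries_a: dict
    expr_b: ExpressionMatrix
    labels_b: dict
    libraries_b: dict
    candidates: pd.DataFrame
    truth: SyntheticTruth
    config: SimConfig = field(repr=False, default=None)


def _sample_counts(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_pair(config: SimConfig) -> SimResult:
    """Generate the two-species datasets, candidate table and ground truth."""
    rng = np.random.default_rng(config.seed)
    n_orth, n_priv = config.n_orthologs, config.n_private_genes
    genes_a = [f"ga{i:05d}" for i in range(n_orth)] + [f"pa{i:04d}" for i in range(n_priv)]
    genes_b_orth = [f"gb{i:05d}" for i in range(n_orth)]
    genes_b = genes_b_orth + [f"pb{i:04d}" for i in range(n_priv)]

    # true map: a random bijection over ortholog slots
    perm = rng.permutation(n_orth)
    true_pairs = [(genes_a[i], genes_b_orth[perm[i]]) for i in range(n_orth)]
    a2b = dict(true_pairs)

    # shared baseline programs on ortholog slots (keyed by the A-side slot)
    base_orth = config.baseline_mean * rng.lognormal(0.0, 1.0, n_orth)
    base_priv = {
        "A": config.baseline_mean * rng.lognormal(0.0, 1.0, n_priv),
        "B": config.baseline_mean * rng.lognormal(0.0, 1.0, n_priv),
    }

    # disjoint marker slots (A-side ortholog indices)
    slots = rng.permutation(n_orth)
    m = config.n_markers_per_type
    marker_slots = {t: slots[k * m : (k + 1) * m] for k, t in enumerate(config.matched_types)}
    unique_slots = {
        "A": slots[config.n_matched * m : (config.n_matched + 1) * m],
        "B": slots[(config.n_matched + 1) * m : (config.n_matched + 2) * m],
    }
    matched_slot_pool = slots[: config.n_matched * m]

    fold = 2.0 ** config.marker_log2fc
    bleed_fold = 2.0 ** (config.marker_log2fc * 0.5)
    n_bleed = int(round(config.continuum_frac * m))
    bleed_slots = marker_slots["type1"][:n_bleed] if config.n_matched >= 2 else []

    # per-type fold vectors on ortholog slots (shared across species), plus
    # an independent idiosyncratic signature for each species-specific type
    type_folds: dict[str, np.ndarray] = {}
    for t in config.matched_types:
        f = np.ones(n_orth)
        f[marker_slots[t]] = fold
        type_folds[t] = f
    if config.n_matched >= 2:
        type_folds["type0"] = type_folds["type0"].copy()
        type_folds["type0"][bleed_slots] = np.maximum(
            type_folds["type0"][bleed_slots], bleed_fold
        )
    unique_folds: dict[str, np.ndarray] = {}
    pool_shuffled = rng.permutation(matched_slot_pool)
    n_down = int(round(config.unique_down_fraction * len(matched_slot_pool) / 2))
    down_slots = {"A": pool_shuffled[:n_down], "B": pool_shuffled[n_down : 2 * n_down]}
    lo, hi = config.unique_down_log2_range
    tilt_target = {
        "A": config.matched_types[-1],
        "B": config.matched_types[-2] if config.n_matched >= 2 else config.matched_types[-1],
    }
    for sp in ("A", "B"):
        f = np.ones(n_orth)
        f[unique_slots[sp]] = fold
        f[down_slots[sp]] = 2.0 ** -rng.uniform(lo, hi, n_down)
        tilt_all = marker_slots[tilt_target[sp]]
        tilt = tilt_all[: int(round(config.unique_tilt_fraction * len(tilt_all)))]
        f[tilt] = np.maximum(
            f[tilt], 2.0 ** (config.unique_tilt_ratio * config.marker_log2fc)
        )
        unique_folds[sp] = f

    lib_mults = np.linspace(
        config.library_depth_range[0],
        config.library_depth_range[1],
        config.libraries_per_species,
    )
    expected_depth = float(np.exp(config.depth_log_sigma**2 / 2) * lib_mults.mean())

    def build_species(sp: str):
        types = config.types(sp)
        gene_ids = genes_a if sp == "A" else genes_b
        n_genes = len(gene_ids)
        # per-gene means on this species' own gene order
        mean_by_type = {}
        markers: dict[str, list[str]] = {}
        for t in types:
            folds = unique_folds[sp] if t == f"unique{sp}" else type_folds[t]
            mu = np.empty(n_genes)
            orth_mu = base_orth * folds
            if sp == "A":
                mu[:n_orth] = orth_mu
            else:
                mu_b = np.empty(n_orth)
                mu_b[perm] = orth_mu  # map A-slot programs onto B gene order
                mu[:n_orth] = mu_b
            mu[n_orth:] = base_priv[sp]
            if t == f"unique{sp}":  # private markers of the species-specific type
                priv_idx = np.arange(n_orth, n_orth + min(m, n_priv))
                mu[priv_idx] = mu[priv_idx] * fold
                marker_gene_list = [gene_ids[i] for i in priv_idx]
                own = unique_slots[sp]
            else:
                marker_gene_list = []
                own = marker_slots[t]
            if sp == "A":
                marker_gene_list += [gene_ids[i] for i in own]
            else:
                marker_gene_list += [gene_ids[perm[i]] for i in own]
            markers[t] = sorted(marker_gene_list)
            mean_by_type[t] = mu

        cells, labels, libraries, cols = [], {}, {}, []
        for t in types:
            for j in range(config.cells_per_type):
                lib = j % config.libraries_per_species
                cid = f"{sp}_{t}_c{j:04d}"
                cells.append(cid)
                labels[cid] = t
                libraries[cid] = f"{sp}_lib{lib}"
                depth = lib_mults[lib] * rng.lognormal(0.0, config.depth_log_sigma)
                cols.append(_sample_counts(rng, mean_by_type[t] * depth,
                                           config.nb_dispersion))
        values = np.column_stack(cols).astype(float)
        expected = pd.DataFrame(
            {t: mean_by_type[t] * expected_depth for t in types}, index=gene_ids
        )
        expr = ExpressionMatrix(values, pd.Index(gene_ids), pd.Index(cells), "raw_counts")
        return expr, labels, libraries, markers, expected

    expr_a, labels_a, libs_a, markers_a, exp_a = build_species("A")
    expr_b, labels_b, libs_b, markers_b, exp_b = build_species("B")

    candidates = _candidate_table(rng, true_pairs, genes_b, config)
    truth = SyntheticTruth(
        planted_pairs={(t, t) for t in config.matched_types},
        markers={"A": markers_a, "B": markers_b},
        ortholog_map=OrthologMap(
            pd.DataFrame(
                sorted(true_pairs), columns=["gene_a", "gene_b"]
            ).assign(rule_applied="truth")
        ),
        expected_mean={"A": exp_a, "B": exp_b},
    )
    return SimResult(
        expr_a, labels_a, libs_a, expr_b, labels_b, libs_b, candidates, truth, config
    )


def _candidate_table(rng, true_pairs, genes_b, config: SimConfig) -> pd.DataFrame:
    """True pairs (top score, reverse flag set) plus lower/tied-score decoys."""
    rows = []
    pool_b = np.asarray(genes_b)
    for a, b in true_pairs:
        score = float(rng.uniform(10.0, 15.0))
        rows.append((a, b, score, True))
        if rng.random() < config.decoy_fraction:
            n_decoys = int(rng.integers(1, 3))
            partners = rng.choice(pool_b, size=n_decoys, replace=False)
            for d in partners:
                if d == b:
                    continue
                if rng.random() < config.decoy_tie_prob:
                    rows.append((a, str(d), score, False))  # tie -> reverse rule decides
                else:
                    rows.append((a, str(d), float(rng.uniform(1.0, score * 0.9)), False))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weighted_score",
                                     "best_score_reverse"])
    return df.drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True)
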