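"""End-to-end orchestration: QC -> orthologs -> aggregation -> matching +
enrichment -> conservation map.

`run_homology` works on in-memory objects (the route tests and the
synthetic-data validation take); `run_pipeline` is the file-driven
wrapper behind the CLI, writing every stage artifact plus a manifest of
parameters, seeds and artifact hashes so a run is reproducible.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as xio
from .aggregate import lognormalize, pseudo_bulk, pseudo_cell
from .conservation import fuse, render_map, truth_metrics
from .markers import find_markers, gsva_scores, translate_markers
from .matrix import ExpressionMatrix, ValidationError
from .orthologs import expressed_orthologs, expression_summary, resolve_orthologs
from .qc import QCThresholds, apply_qc, qc_records
from .simulate import SimResult
from .voting import auroc_matrix, merge_profiles, top_hits, variable_genes, voting_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full cross-species run (the shipped defaults are the
    study constants: min.pct 0.25, adjusted p 0.05, hit threshold 0.80 —
    0.75 when the simpler species is involved — retention strictly > 0.80)."""

    expr_a: str = ""
    expr_b: str = ""
    labels_a: str = ""
    labels_b: str = ""
    candidates: str = ""
    out_dir: str = "xsp_out"
    scale_a: str = "raw_counts"
    scale_b: str = "raw_counts"
    qc: dict = field(default_factory=dict)      # QCThresholds kwargs
    skip_qc: bool = False
    group_size: int = 10
    hit_threshold: float = 0.80
    retention_threshold: float = 0.80
    min_pct: float = 0.25
    alpha: float = 0.05
    min_set_size: int = 5
    min_cells_expressed: int = 1
    seed: int = 0


def _qc_filter(expr: ExpressionMatrix, labels: dict, libraries: dict,
               thresholds: QCThresholds):
    rec = qc_records(expr, library=libraries)
    res = apply_qc(rec, thresholds)
    kept = set(res.kept)
    keep_mask = [c in kept for c in expr.cells]
    idx = [i for i, k in enumerate(keep_mask) if k]
    filtered = ExpressionMatrix(
        expr.values[:, idx], expr.genes, expr.cells[keep_mask], expr.scale
    )
    return filtered, res


def run_homology(
    expr_a: ExpressionMatrix,
    labels_a: dict,
    libraries_a: dict,
    expr_b: ExpressionMatrix,
    labels_b: dict,
    libraries_b: dict,
    candidates: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Run the full comparison on in-memory inputs; return stage artifacts."""
    cfg = config or RunConfig()

    if not cfg.skip_qc and expr_a.scale == "raw_counts":
        thr = QCThresholds(**cfg.qc) if cfg.qc else QCThresholds()
        expr_a, qc_a = _qc_filter(expr_a, labels_a, libraries_a, thr)
        expr_b, qc_b = _qc_filter(expr_b, labels_b, libraries_b, thr)
    else:
        qc_a = qc_b = None

    summ_a = expression_summary(expr_a)
    summ_b = expression_summary(expr_b)
    omap = resolve_orthologs(candidates, summ_a, summ_b)
    omap = expressed_orthologs(omap, summ_a, summ_b, cfg.min_cells_expressed)
    if len(omap) == 0:
        raise ValidationError("no expressed orthologs between the datasets")

    ln_a = lognormalize(expr_a) if expr_a.scale == "raw_counts" else expr_a
    ln_b = lognormalize(expr_b) if expr_b.scale == "raw_counts" else expr_b

    # unsupervised arm: pseudo-cells over the shared ortholog space
    b2a = {b: a for a, b in omap.pairs}
    sub_a = ln_a.subset_genes(omap.table["gene_a"].tolist())
    sub_b = ln_b.subset_genes(omap.table["gene_b"].tolist()).rename_genes(b2a)
    pc_a = pseudo_cell(sub_a, labels_a, cfg.group_size, cfg.seed, "A", libraries_a)
    pc_b = pseudo_cell(sub_b, labels_b, cfg.group_size, cfg.seed + 1, "B", libraries_b)
    hvg = variable_genes([pc_a, pc_b])
    merged = merge_profiles(pc_a, pc_b, hvg)
    net = voting_network(merged)
    auroc = auroc_matrix(net, merged.meta[["dataset", "cell_type"]])
    hits = top_hits(auroc, cfg.hit_threshold)

    # supervised arm: species-A marker sets scored on species-B pseudo-bulk
    catalog = find_markers(ln_a, labels_a, cfg.min_pct, cfg.alpha)
    translated = translate_markers(catalog, omap)
    pb_b = pseudo_bulk(ln_b, labels_b, "B")
    enrich = gsva_scores(pb_b, translated, cfg.min_set_size)
    enrich.data.columns = [pb_b.meta.at[p, "cell_type"] for p in enrich.data.columns]

    cons = fuse(auroc, enrich, hits.reciprocal_pairs, cfg.retention_threshold)
    return {
        "network": net,
        "merged_meta": merged.meta,
        "qc": {"A": qc_a, "B": qc_b},
        "ortholog_map": omap,
        "variable_genes": hvg,
        "auroc": auroc,
        "hits": hits,
        "catalog": catalog,
        "translated_catalog": translated,
        "enrichment": enrich,
        "conservation": cons,
    }


def permutation_null(result: dict, n_permutations: int = 20, seed: int = 0) -> list[float]:
    """Mean pairwise AUROC under shuffled cell-type labels, per permutation.

    Labels are permuted within each dataset over the already-built
    voting network, so the null isolates the label/vote association.
    """
    import numpy as np

    net = result["network"]
    meta = result["merged_meta"][["dataset", "cell_type"]].copy()
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_permutations):
        shuffled = meta.copy()
        for ds in shuffled["dataset"].unique():
            mask = shuffled["dataset"] == ds
            vals = shuffled.loc[mask, "cell_type"].to_numpy()
            shuffled.loc[mask, "cell_type"] = vals[rng.permutation(len(vals))]
        sm = auroc_matrix(net, shuffled)
        means.append(float(np.nanmean(sm.data.to_numpy())))
    return means


def evaluate_against_truth(result: dict, sim: SimResult) -> dict:
    """Recovery metrics of a pipeline run against the planted ground truth."""
    metrics = truth_metrics(result["conservation"], sim.truth.planted_pairs)
    resolved = result["ortholog_map"].pairs
    true_pairs = sim.truth.ortholog_map.pairs
    metrics["ortholog_accuracy"] = (
        len(resolved & true_pairs) / len(resolved) if resolved else 0.0
    )
    uniques = {f"unique{s}" for s in "AB"}
    metrics["unique_type_retained"] = bool(
        result["conservation"]
        .query("retained")[["type_a", "type_b"]]
        .isin(uniques)
        .any(axis=None)
    )
    return metrics


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """File-driven run: read inputs, execute all stages, write artifacts."""
    for name in ("expr_a", "expr_b", "labels_a", "labels_b", "candidates"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise ValidationError(f"missing input file for {name}: {p!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    expr_a = _stage("read_a", xio.read_expression, config.expr_a, config.scale_a)
    expr_b = _stage("read_b", xio.read_expression, config.expr_b, config.scale_b)
    labels_a, libs_a = _stage("labels_a", xio.read_labels, config.labels_a)
    labels_b, libs_b = _stage("labels_b", xio.read_labels, config.labels_b)
    candidates = _stage("candidates", xio.read_candidates, config.candidates)

    result = _stage(
        "analysis", run_homology,
        expr_a, labels_a, libs_a, expr_b, labels_b, libs_b, candidates, config,
    )

    xio.write_ortholog_map(result["ortholog_map"], out / "ortholog_map.tsv")
    result["auroc"].data.to_csv(out / "auroc.csv")
    result["hits"].records.to_csv(out / "top_hits.tsv", sep="\t", index=False)
    result["catalog"].to_frame().to_csv(out / "markers.tsv", sep="\t", index=False)
    result["enrichment"].data.to_csv(out / "enrichment.csv")
    result["conservation"].to_csv(out / "conservation_map.csv", index=False)
    retained = render_map(result["conservation"], "A", "B",
                          figure_path=str(out / "conservation_map.png"))
    retained.to_csv(out / "retained_pairs.csv", index=False)

    artifacts = sorted(
        p.name for p in out.iterdir()
        if p.is_file() and p.suffix != ".png" and p.name != "manifest.json"
    )
    manifest = {
        "parameters": asdict(config),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    xio.write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %d retained pairs", len(retained))
    result["manifest"] = manifest
    return result
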