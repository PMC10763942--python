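"""Readers and writers for the standard formats the pipeline touches.

Expression matrices travel either as MatrixMarket triplets with gene and
cell TSV sidecars (the droplet-data deposition convention) or as dense
CSV with genes in rows. A ``metadata.yaml`` sidecar may carry the scale
flag. Gene identifiers are opaque strings throughout.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix, PseudoProfileMatrix, ValidationError
from .orthologs import CANDIDATE_COLUMNS, OrthologMap


def read_expression(path: str | Path, scale: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from an MTX directory or a dense CSV."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise ValidationError(f"{path} has no matrix.mtx")
        values = spio.mmread(mtx)
        if sparse.issparse(values):
            values = values.toarray()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        meta = path / "metadata.yaml"
        if scale is None and meta.exists():
            scale = yaml.safe_load(meta.read_text()).get("scale")
    elif path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        genes, cells = df.index.tolist(), df.columns.tolist()
    else:
        raise ValidationError(f"unsupported expression input: {path}")
    return ExpressionMatrix(np.asarray(values, dtype=float), pd.Index(genes),
                            pd.Index(cells), scale or "raw_counts")


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     fmt: str = "mtx") -> None:
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(matrix.values))
        pd.Series(matrix.genes).to_csv(path / "genes.tsv", sep="\t",
                                       header=False, index=False)
        pd.Series(matrix.cells).to_csv(path / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
        (path / "metadata.yaml").write_text(yaml.safe_dump({"scale": matrix.scale}))
    elif fmt == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(path)
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Ortholog candidate TSV: gene_a, gene_b, weighted_score, best_score_reverse."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"candidate TSV missing columns: {missing}")
    return df


def write_candidates(candidates: pd.DataFrame, path: str | Path) -> None:
    out = candidates.copy()
    out["best_score_reverse"] = np.where(out["best_score_reverse"], "Yes", "No")
    out.to_csv(path, sep="\t", index=False)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.table.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t"))


def write_profiles(profiles: PseudoProfileMatrix, prefix: str | Path) -> None:
    """Profiles as genes x profiles CSV plus a profile-metadata TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    profiles.to_frame().to_csv(f"{prefix}.csv")
    meta = profiles.meta.copy()
    meta["members"] = [";".join(m) for m in meta["members"]]
    meta.insert(0, "kind", profiles.kind)
    meta.to_csv(f"{prefix}.meta.tsv", sep="\t")


def read_labels(path: str | Path) -> tuple[dict, dict]:
    """Cell annotation TSV (cell_id, library, cell_type) -> labels, libraries."""
    df = pd.read_csv(path, sep="\t")
    need = {"cell_id", "cell_type"}
    if not need.issubset(df.columns):
        raise ValidationError(f"annotation table needs columns {sorted(need)}")
    labels = dict(zip(df["cell_id"], df["cell_type"]))
    libs = (
        dict(zip(df["cell_id"], df["library"])) if "library" in df.columns else {}
    )
    return labels, libs


def write_labels(labels: dict, libraries: dict, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": list(labels),
            "library": [libraries.get(c, "lib0") for c in labels],
            "cell_type": [labels[c] for c in labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
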