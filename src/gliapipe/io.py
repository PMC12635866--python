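"""Reading and writing the pipeline's on-disk formats.

Counts travel as MatrixMarket (matrix.mtx + genes.tsv + barcodes.tsv)
or dense TSV; tables (cells, composition, histology, results) as TSV;
shape point clouds as long-format CSV (object_id, mouse_id, region,
x, y, z in micrometres); configuration as YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

FLOAT_FORMAT = "%.10g"


def write_counts(counts, gene_names, barcodes, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts))
    pd.Series(gene_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_counts(indir):
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return X, genes, barcodes


def read_dense_counts(path):
    """Dense TSV dialect: genes in rows (index), cells in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return sparse.csr_matrix(df.to_numpy()), df.index.tolist(), df.columns.tolist()


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_shapes(shapes, path) -> None:
    """Long-format CSV of shape point clouds."""
    rows = []
    for s in shapes:
        for x, y, z in s.points:
            rows.append((s.object_id, s.mouse_id, s.region, s.label, x, y, z))
    df = pd.DataFrame(rows, columns=["object_id", "mouse_id", "region", "label", "x", "y", "z"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_shapes(path) -> list[dict]:
    df = pd.read_csv(path)
    shapes = []
    for oid, grp in df.groupby("object_id", sort=False):
        shapes.append(
            {
                "object_id": oid,
                "mouse_id": grp["mouse_id"].iloc[0],
                "region": grp["region"].iloc[0],
                "label": grp["label"].iloc[0] if "label" in grp else None,
                "points": grp[["x", "y", "z"]].to_numpy(float),
            }
        )
    return shapes


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True).encode()
    ).hexdigest()
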