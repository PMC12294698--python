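"""On-disk formats: BED, MatrixMarket + row/column TSVs, gene-model TSV,
plain TSV tables, ground-truth JSON.

All coordinates on disk are 0-based half-open (BED convention), including
the gene-model TSV. Floats are written with a fixed format so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_bed(df: pd.DataFrame, path: Path, name_col: str = "peak_id",
              score_col: str | None = None) -> None:
    """BED6 writer; score 0 unless ``score_col`` given, strand '.'."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df[name_col],
        "score": df[score_col] if score_col else 0,
        "strand": df["strand"] if "strand" in df.columns else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format=FLOAT_FMT)


def read_bed(path: Path, name: str = "peak_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", name, "score", "strand"][: df.shape[1]]
    return df


def write_matrix(X, row_ids, col_ids, path_prefix: Path) -> None:
    """Matrix as <prefix>.mtx plus <prefix>_rows.tsv / <prefix>_cols.tsv."""
    path_prefix = Path(path_prefix)
    spio.mmwrite(str(path_prefix) + ".mtx", sparse.csr_matrix(np.asarray(X)))
    pd.Series(list(row_ids)).to_csv(str(path_prefix) + "_rows.tsv",
                                    sep="\t", index=False, header=False)
    pd.Series(list(col_ids)).to_csv(str(path_prefix) + "_cols.tsv",
                                    sep="\t", index=False, header=False)


def read_matrix(path_prefix: Path) -> tuple[np.ndarray, list[str], list[str]]:
    path_prefix = Path(path_prefix)
    X = spio.mmread(str(path_prefix) + ".mtx").toarray()
    rows = pd.read_csv(str(path_prefix) + "_rows.tsv", sep="\t",
                       header=None)[0].astype(str).tolist()
    cols = pd.read_csv(str(path_prefix) + "_cols.tsv", sep="\t",
                       header=None)[0].astype(str).tolist()
    return X, rows, cols


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: Path):
    return json.loads(Path(path).read_text())
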