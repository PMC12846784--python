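"""Plain-text readers/writers for the pipeline's tables and matrices."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .cellgraph import CellMap, canonicalize_feature_names


def write_cell_map_csv(cm: CellMap, path) -> None:
    cm.to_frame().to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a samples x features CSV; ``sd`` feature-name aliases are
    canonicalised to ``variance``."""
    df = pd.read_csv(path, index_col=0)
    df.columns = canonicalize_feature_names(df.columns)
    return df


def read_survival(path) -> pd.DataFrame:
    """Read a survival CSV with patient_id, time, event (and cohort)."""
    df = pd.read_csv(path, index_col=0)
    if "cohort" not in df.columns:
        df["cohort"] = "default"
    return df[["time", "event", "cohort"]]


def write_expression(expr: pd.DataFrame, prefix) -> None:
    """Write a cells x genes matrix as MTX + barcodes/features TSVs."""
    os.makedirs(prefix, exist_ok=True)
    mmwrite(os.path.join(prefix, "matrix.mtx"),
            csr_matrix(expr.to_numpy(dtype=float).T))
    with open(os.path.join(prefix, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, expr.index)) + "\n")
    with open(os.path.join(prefix, "features.tsv"), "w") as fh:
        fh.write("\n".join(map(str, expr.columns)) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Read a cells x genes matrix from an MTX directory or a dense CSV."""
    if os.path.isdir(path):
        mat = mmread(os.path.join(path, "matrix.mtx")).toarray().T
        barcodes = np.loadtxt(os.path.join(path, "barcodes.tsv"), dtype=str)
        features = np.loadtxt(os.path.join(path, "features.tsv"), dtype=str)
        return pd.DataFrame(mat, index=barcodes, columns=features)
    return pd.read_csv(path, index_col=0)
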