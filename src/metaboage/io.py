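"""Plain-text table readers and writers.

All on-disk artifacts are tab-separated text so that every intermediate is
inspectable and diffable.  Matrices carry the sample identifier in the first
column and variable names in the header row.  Relatedness matrices use the
PLINK-style ``.rel`` / ``.rel.id`` pair (square tab-delimited matrix plus a
one-column id file).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

INDEX_NAME = "sample_id"


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or INDEX_NAME
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_rel(K: np.ndarray, ids: list[str], path: str | Path) -> None:
    """Write a square relatedness matrix as ``<path>`` with ids in ``<path>.id``."""
    path = Path(path)
    np.savetxt(path, K, delimiter="\t", fmt="%.10g")
    Path(str(path) + ".id").write_text("\n".join(map(str, ids)) + "\n")


def read_rel(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    K = np.loadtxt(path, delimiter="\t")
    ids = Path(str(path) + ".id").read_text().split()
    if K.shape[0] != K.shape[1] or K.shape[0] != len(ids):
        raise ValueError(
            f"relatedness matrix {K.shape} does not match {len(ids)} ids"
        )
    return K, ids


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
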