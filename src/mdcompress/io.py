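"""Table I/O shared by the CLI subcommands.

Two interchangeable on-disk forms: TSV with a header row of labels (text,
round-trips to >= 12 significant digits) and an ``.npz`` container (exact
binary round-trip).  Either form carries a JSON sidecar ``<file>.meta.json``
with the column labels, the frame time step and any provenance (seeds,
architectures).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = ["write_table", "read_table", "write_json", "read_json"]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_table(path, matrix: FeatureMatrix) -> Path:
    """Write a FeatureMatrix as TSV (.tsv/.txt) or npz (.npz) + sidecar."""
    path = Path(path)
    if len(matrix.labels) != matrix.values.shape[1]:
        raise ValueError("label count does not match column count")
    if path.suffix == ".npz":
        np.savez(path, values=matrix.values)
    elif path.suffix in (".tsv", ".txt"):
        matrix.to_frame().to_csv(path, sep="\t", index=False,
                                 float_format="%.17g")
    else:
        raise ValueError(f"unsupported table extension {path.suffix!r}")
    write_json(_sidecar(path), {
        "labels": list(matrix.labels),
        "timestep_ns": matrix.timestep_ns,
        "meta": matrix.meta,
    })
    return path


def read_table(path) -> FeatureMatrix:
    """Read a table written by :func:`write_table` (sidecar optional)."""
    path = Path(path)
    side = _sidecar(path)
    info = read_json(side) if side.exists() else {}
    if path.suffix == ".npz":
        with np.load(path) as data:
            values = data["values"]
        labels = info.get("labels")
    elif path.suffix in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t")
        labels = info.get("labels", list(map(str, df.columns)))
        values = df.to_numpy(dtype=np.float64)
        if values.size == 0:
            values = np.empty((len(df), len(df.columns)))
    else:
        raise ValueError(f"unsupported table extension {path.suffix!r}")
    return FeatureMatrix(values, labels, info.get("timestep_ns", 1.0),
                         info.get("meta", {}))
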