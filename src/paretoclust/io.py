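"""Delimited-text readers and result writers for the command-line surface.

Data matrices are plain delimited text (comma, tab or whitespace, detected
automatically; an optional single non-numeric header row is skipped), as used
by the common clustering benchmark collections.  Ground-truth partitions are
one integer label per line.  Fit results round-trip through a labels file and
a JSON document carrying the full parameter set at 17 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import ClusterParams
from .estimate import FitResult

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "read_labels", "write_result", "read_result_params"]


def _detect(path: Path):
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file or blank first line")
    sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
    tokens = first.strip().split("," if sep == "," else None)
    try:
        [float(t) for t in tokens]
        header = None
    except ValueError:
        header = 0
    return sep, header


def read_matrix(path) -> np.ndarray:
    """Read an (n, d) numeric matrix from delimited text."""
    path = Path(path)
    sep, header = _detect(path)
    try:
        df = pd.read_csv(path, sep=sep, header=header, engine="python",
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise ValueError(f"{path}: non-numeric cell at row {i + 1}, column {j + 1}")
        df[col] = vals
    X = df.to_numpy(dtype=float)
    logger.info("read %d rows x %d columns from %s", *X.shape, path)
    return X


def read_labels(path) -> np.ndarray:
    """Read one integer label per line; values are remapped to 1..L."""
    path = Path(path)
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                raw.append(int(float(s)))
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer label on line {lineno}: {s!r}") from exc
    raw = np.asarray(raw, dtype=int)
    uniq, remapped = np.unique(raw, return_inverse=True)
    if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
        logger.info("remapped labels %s -> 1..%d", uniq.tolist(), len(uniq))
    return remapped + 1


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, float)):
        return float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def write_result(result: FitResult, outdir, hyper=None, seed=None) -> dict:
    """Write labels (one per line) and a JSON document with the fitted
    parameters, run controls and the full energy trace; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels_path = outdir / "labels.txt"
    labels_path.write_text("\n".join(str(int(l)) for l in result.labels) + "\n")
    doc = {
        "centers": result.params.centers.tolist(),
        "covariances": result.params.covariances.tolist(),
        "proportions": result.params.proportions.tolist(),
        "n_iter": int(result.n_iter),
        "converged": bool(result.converged),
        "n_reseeds": int(result.n_reseeds),
        "energy_trace": result.energy_trace.tolist(),
    }
    if hyper is not None:
        doc["hyperparams"] = {
            k: ("inf" if isinstance(v, float) and math.isinf(v) else _jsonify(v))
            for k, v in vars(hyper).items()
        }
    if seed is not None:
        doc["seed"] = int(seed)
    json_path = outdir / "result.json"
    json_path.write_text(json.dumps(doc, indent=1) + "\n")
    logger.info("wrote %s and %s", labels_path, json_path)
    return {"labels": labels_path, "result": json_path}


def read_result_params(path) -> ClusterParams:
    """Re-read the fitted parameters from a result JSON document."""
    doc = json.loads(Path(path).read_text())
    return ClusterParams(
        np.asarray(doc["centers"], dtype=float),
        np.asarray(doc["covariances"], dtype=float),
        np.asarray(doc["proportions"], dtype=float),
    )
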