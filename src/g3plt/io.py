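"""CSV interchange for response/time matrices, item tables and results.

All public artifacts are plain CSV: matrices carry a header row of item
IDs and a first column of person IDs; item-parameter tables have columns
``item,a,b,c``.  Every writer also drops a JSON sidecar
(``<name>.meta.json``) recording the package version, seed and a config
hash so an artifact can be regenerated exactly.  Posterior draws go to a
compressed ``.npz`` with arrays ``theta``, ``a``, ``b``, ``c``,
``chain`` plus scalar ``D``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import ItemParams, ResponseMatrix, TimeMatrix
from .sampler import PosteriorDraws

__all__ = [
    "read_matrix_csv", "write_matrix_csv",
    "read_item_params", "write_item_params",
    "save_draws", "load_draws", "write_summary",
]

_KINDS = ("response", "time", "tstar")


def read_matrix_csv(path, kind: str = "response"):
    """Read an N x J matrix CSV (person IDs in column 1, item IDs in header).

    ``kind`` controls validation: ``response`` requires 0/1 cells,
    ``time`` strictly positive cells, ``tstar`` finite cells.  Returns
    ``(values, person_ids, item_ids)``.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at row {df.index[i]!r}, column {df.columns[j]!r}")
    if kind == "response" and not np.isin(values, (0, 1)).all():
        i, j = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValueError(
            f"response cell must be 0/1 at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}")
    if kind == "time" and np.any(values <= 0):
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"time cell must be positive at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}")
    if kind == "response":
        values = values.astype(np.int8)
    return values, list(df.index), list(df.columns)


def write_matrix_csv(values, path, person_ids=None, item_ids=None, meta=None):
    values = np.asarray(values)
    n, j = values.shape
    person_ids = person_ids or [f"p{i+1}" for i in range(n)]
    item_ids = item_ids or [f"item{k+1}" for k in range(j)]
    df = pd.DataFrame(values, index=person_ids, columns=item_ids)
    df.index.name = "id"
    df.to_csv(path, float_format="%.6g")
    _write_meta(path, meta)
    return Path(path)


def read_item_params(path, D: float = 1.7) -> ItemParams:
    df = pd.read_csv(path)
    missing = {"a", "b", "c"} - set(df.columns)
    if missing:
        raise ValueError(f"item table missing columns: {sorted(missing)}")
    return ItemParams(a=df["a"].to_numpy(), b=df["b"].to_numpy(),
                      c=df["c"].to_numpy(), D=D)


def write_item_params(items: ItemParams, path, meta=None):
    df = pd.DataFrame({
        "item": [f"item{k+1}" for k in range(items.J)],
        "a": items.a, "b": items.b, "c": items.c,
    })
    df.to_csv(path, index=False, float_format="%.6g")
    _write_meta(path, meta)
    return Path(path)


def save_draws(draws: PosteriorDraws, path, meta=None):
    path = Path(path)
    np.savez_compressed(path, theta=draws.theta, a=draws.a, b=draws.b,
                        c=draws.c, chain=draws.chain, D=np.array(draws.D))
    _write_meta(path, dict(meta or {}, acceptance=draws.acceptance))
    return path


def load_draws(path) -> PosteriorDraws:
    with np.load(path) as z:
        return PosteriorDraws(theta=z["theta"], a=z["a"], b=z["b"], c=z["c"],
                              chain=z["chain"], D=float(z["D"]))


def write_summary(df: pd.DataFrame, path, meta=None):
    """Write a result table with stable column order and 6-sig-digit floats."""
    df.to_csv(path, index=False, float_format="%.6g")
    _write_meta(path, meta)
    return Path(path)


def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_meta(path, meta: Optional[dict]) -> None:
    from . import __version__

    record = {"g3plt_version": __version__}
    if meta:
        record.update(meta)
        record["config_hash"] = _config_hash(meta)
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(record, indent=1, sort_keys=True, default=str))
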