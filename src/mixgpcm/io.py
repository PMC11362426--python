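"""CSV / JSON / YAML input-output for response matrices, models and configs.

The canonical on-disk layout for responses is a wide CSV: a header row of
item names and one row per person, integer category codes, empty cells (or a
configurable token) for missing responses.  Long-format files (person, item,
response columns) can be imported via ``read_responses_csv(..., long=True)``.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd
import yaml

from .parameters import MISSING, RatingScale, ResponseMatrix

__all__ = [
    "read_responses_csv",
    "write_responses_csv",
    "load_config",
    "save_report",
    "provenance",
]


def read_responses_csv(path, n_categories: int | None = None,
                       missing_token: str = "", long: bool = False) -> ResponseMatrix:
    """Read a wide (default) or long response CSV into a ResponseMatrix.

    Every cell must be an integer in 0..m or the missing token; violations
    raise with the offending row and column named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if long:
        if not {"person", "item", "response"} <= set(df.columns):
            raise ValueError("long format needs 'person', 'item', 'response' columns")
        df = df.pivot(index="person", columns="item", values="response")
        df = df.reset_index(drop=True)
    n_rows, n_cols = df.shape
    data = np.full((n_rows, n_cols), MISSING, dtype=int)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].tolist()):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                continue
            try:
                value = int(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-integer response {cell!r} at row {i + 1}, column {col!r}"
                ) from exc
            data[i, j] = value
    if n_categories is None:
        n_categories = int(data.max()) + 1
    scale = RatingScale(n_categories)
    out_of_range = (data != MISSING) & ((data < 0) | (data > scale.m))
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"response code {data[i, j]} at row {i + 1}, column {df.columns[j]!r} "
            f"is outside 0..{scale.m}"
        )
    return ResponseMatrix(data, scale, item_names=list(df.columns))


def write_responses_csv(data: ResponseMatrix, path, missing_token: str = "") -> None:
    df = pd.DataFrame(data.values.astype(object), columns=data.item_names)
    df = df.mask(df == MISSING, missing_token)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration with basic validation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" in cfg and int(cfg["seed"]) < 0:
        raise ValueError("seed must be nonnegative")
    if "class_range" in cfg:
        cr = cfg["class_range"]
        if not all(isinstance(g, int) and g >= 1 for g in cr):
            raise ValueError("class_range must be positive integers")
    return cfg


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Version / config-hash / seed stamp attached to every written artifact."""
    try:
        ver = version("mixgpcm")
    except PackageNotFoundError:
        ver = "unknown"
    stamp = {"package": "mixgpcm", "version": ver}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        stamp["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    if seed is not None:
        stamp["seed"] = int(seed)
    return stamp


def save_report(report: dict, path, config: dict | None = None,
                seed: int | None = None) -> None:
    payload = {"provenance": provenance(config, seed), "report": report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return str(obj)
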