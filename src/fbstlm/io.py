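"""CSV/config/JSON plumbing for the command-line workflow.

CSV datasets have a header row, one named response column, and numeric
covariate columns; missing values are an error (no silent imputation).
Configuration files are flat YAML key-value mappings; command-line flags
override config values.  Result JSON carries the full audit trail (priors,
Monte Carlo sizes, seed) so a run can be reproduced from its output alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conjugate import RegressionData

__all__ = ["read_regression_csv", "load_config", "save_json", "resolve_tested"]


def read_regression_csv(path, response: str, intercept: bool = True):
    """Load a regression dataset from CSV.

    Returns ``(RegressionData, names)`` where ``names`` labels the design
    columns (starting with ``"intercept"`` when one is added).
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(
            f"response column {response!r} not found in {path}; "
            f"available: {', '.join(df.columns)}"
        )
    covs = df.drop(columns=[response])
    bad = [c for c in df.columns if df[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in column(s): {', '.join(bad)}")
    try:
        X = covs.to_numpy(dtype=float)
        y = df[response].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    names = list(covs.columns)
    if intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["intercept"] + names
    return RegressionData(X, y), names


def resolve_tested(spec, names: "list[str]") -> "list[int]":
    """Map a tested-coefficient spec (``"each"``, indices, or column names)
    onto design-column indices."""
    if spec is None or (isinstance(spec, str) and spec.strip().lower() == "each"):
        return list(range(len(names)))
    if isinstance(spec, str):
        items = [s.strip() for s in spec.split(",") if s.strip()]
    else:
        items = list(np.atleast_1d(spec))
    out = []
    for item in items:
        if isinstance(item, str) and not item.lstrip("-").isdigit():
            if item not in names:
                raise ValueError(f"tested column {item!r} not among {names}")
            out.append(names.index(item))
        else:
            j = int(item)
            if not 0 <= j < len(names):
                raise ValueError(f"tested index {j} out of range [0, {len(names)})")
            out.append(j)
    if not out:
        raise ValueError("tested set must be nonempty")
    return out


def load_config(path) -> dict:
    """Flat YAML key-value config; nested mappings are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    for key, value in cfg.items():
        if isinstance(value, dict):
            raise ValueError(f"config key {key!r} is nested; use flat keys")
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(payload: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
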