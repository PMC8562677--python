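"""Cohort CSV reading/writing and config handling.

Cohort files are plain CSV with header ``x1..xp,a,y,z``; treatment `a`
takes values -1/+1 (files coded 0/1 are recoded with a logged notice) and
missing values are rejected with the offending row named.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohorts import CohortData, GenerativeConfig

logger = logging.getLogger("utilitr")


class CohortParseError(ValueError):
    """The cohort file violates the expected schema."""


def read_cohort(path: str | Path) -> CohortData:
    """Read and validate a cohort CSV.

    Treatment coded {0, 1} is recoded to {-1, +1} with a logged notice.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise CohortParseError(f"cannot parse {path}: {exc}") from exc
    xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    missing = [c for c in ("a", "y", "z") if c not in df.columns]
    if missing or not xcols:
        raise CohortParseError(
            f"{path}: missing columns {missing or ['x1..xp']}; "
            f"expected header x1..xp,a,y,z")
    sub = df[xcols + ["a", "y", "z"]]
    try:
        values = sub.astype(float)
    except (TypeError, ValueError) as exc:
        raise CohortParseError(f"{path}: non-numeric cell ({exc})") from exc
    bad = values.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise CohortParseError(f"{path}: missing value in row {row}")
    a = values["a"].to_numpy()
    if set(np.unique(a)) <= {0.0, 1.0}:
        logger.info("treatment column coded {0,1}; recoding to {-1,+1}")
        a = 2.0 * a - 1.0
    if not np.all(np.isin(a, (-1.0, 1.0))):
        row = int(np.argmax(~np.isin(a, (-1.0, 1.0))))
        raise CohortParseError(f"{path}: treatment outside {{-1,0,1}} in row {row}")
    return CohortData(values[xcols].to_numpy(), a,
                      values["y"].to_numpy(), values["z"].to_numpy())


def write_cohort(data: CohortData, path: str | Path) -> None:
    data.to_dataframe().to_csv(path, index=False)


def config_to_dict(config: GenerativeConfig) -> dict:
    d = {}
    for k, v in config.__dict__.items():
        d[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return d


def read_config(path: str | Path) -> GenerativeConfig:
    """Load a GenerativeConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return GenerativeConfig(**raw)


def write_config(config: GenerativeConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
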