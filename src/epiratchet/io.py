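"""TIFF stacks and CSV measurement tables.

Images travel as multi-page TIFF (16-bit labels, float or integer
intensity); every measurement table is CSV for diff-ability.  Table
schemas are versioned through a ``schema`` comment column written by
``write_tables``.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, InvalidInputError

SCHEMA_VERSION = 1


def read_stack(path) -> np.ndarray:
    """Read a TIFF stack as a (T, H, W) array of time-ordered frames."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as e:
        raise InvalidInputError(f"cannot read TIFF {path}: {e}") from e
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError(
            f"{path}: expected a 2D frame or 3D stack, got shape {arr.shape}")
    return arr


def write_stack(path, stack: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(stack)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.max() >= 2 ** 16 or arr.min() < 0:
            raise InvalidInputError("label values do not fit uint16")
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Write each DataFrame as <name>.csv; returns name -> sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return checksums


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(path, summary: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg
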