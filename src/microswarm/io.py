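"""File formats: multi-page 8-bit TIFF stacks, CSV tables, YAML configs.

Tables are comma-separated UTF-8 with '.' decimals and a header row;
provenance (config hash, seed, stage) is written as ``# key: value``
comment lines above the header and skipped transparently on read.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class SchemaError(ValueError):
    """A table is missing a required column."""


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, rows, cols) 8-bit stack as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.dtype != np.uint8:
        raise ValueError("stack must be uint8")
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(str(path), stack)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as an 8-bit stack.

    Non-8-bit input is linearly rescaled to [0, 255] with a warning.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype != np.uint8:
        warnings.warn(f"{path}: converting {arr.dtype} stack to 8-bit by "
                      "linear rescale", stacklevel=2)
        arr = arr.astype(float)
        lo, hi = arr.min(), arr.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        arr = np.clip(np.rint((arr - lo) * scale), 0, 255).astype(np.uint8)
    return arr


def write_table(df: pd.DataFrame, path: str | Path,
                provenance: dict | None = None) -> None:
    """Write a CSV table with optional ``# key: value`` provenance lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path,
               required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, skipping provenance comments.

    Raises :class:`SchemaError` naming the first missing required column.
    """
    df = pd.read_csv(path, comment="#")
    for col in required or []:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj: dict) -> str:
    """Short stable hash of a config mapping (for provenance headers)."""
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]
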