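"""Reading and writing the pipeline's file formats.

Cohorts are comma-delimited text with a header row, dot decimals and empty
fields for missing values; parameter blocks and model bundles are YAML.
Every file written by the package starts with comment lines recording the
package version, the seed of the run and SHA-256 hashes of its inputs, so
a result can always be traced to the exact artifacts that produced it.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .rates import RateTable

logger = logging.getLogger("densrisk")

EVENT_CODES = {
    "invasive_bc", "in_situ_bc", "other_cancer", "mastectomy",
    "death", "age80", "admin_censor",
}

_PERCENT_COLS = ("pmd", "pvd")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _header_lines(seed=None, inputs=()) -> str:
    lines = [f"# densrisk v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for p in inputs:
        lines.append(f"# input {Path(p).name} sha256: {file_sha256(p)}")
    return "\n".join(lines) + "\n"


def write_cohort(cohort: pd.DataFrame, path, seed=None, inputs=()):
    """Write a cohort table as commented CSV (empty field = missing)."""
    with open(path, "w") as f:
        f.write(_header_lines(seed, inputs))
        cohort.to_csv(f, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; raises with the offending row number.

    Checks: known event codes, positive follow-up time, non-negative ages,
    percent densities within [0, 100].  Missing fields stay missing (NaN),
    never 0.
    """
    df = pd.read_csv(path, comment="#")
    logger.info("read %d cohort rows from %s", len(df), path)

    def _fail(mask, message):
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise ValueError(f"{message} (first offending row {row}, id "
                             f"{df['id'].iloc[row] if 'id' in df else row})")

    if "event" in df:
        _fail(~df["event"].isin(EVENT_CODES) & df["event"].notna(),
              "unknown event code")
    if "time" in df:
        _fail(df["time"].notna() & (df["time"] <= 0), "non-positive follow-up time")
    if "age_entry" in df:
        _fail(df["age_entry"].notna() & (df["age_entry"] < 0), "negative age")
    for col in _PERCENT_COLS:
        if col in df:
            _fail(df[col].notna() & ((df[col] < 0) | (df[col] > 100)),
                  f"{col} outside [0, 100]")
    return df


def _to_native(obj):
    """Recursively convert numpy scalars/arrays so YAML can represent them."""
    if isinstance(obj, dict):
        return {_to_native(k): _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _to_native(obj.tolist())
    return obj


def write_yaml(obj: dict, path, seed=None, inputs=()):
    """Write a parameter block / model bundle as YAML with a meta header."""
    obj = _to_native(obj)
    payload = {
        "meta": {
            "package_version": __version__,
            "seed": seed,
            "inputs": {Path(p).name: file_sha256(p) for p in inputs},
        },
        **obj,
    }
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as f:
        d = yaml.safe_load(f)
    d.pop("meta", None)
    return d


def write_rates(table: RateTable, path, seed=None):
    with open(path, "w") as f:
        f.write(_header_lines(seed))
        table.to_frame().to_csv(f, index=False)


def read_rates(path) -> RateTable:
    return RateTable.from_frame(pd.read_csv(path, comment="#"))
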