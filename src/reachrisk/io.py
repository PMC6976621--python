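"""Trial-table CSV dialect and run configuration.

The interchange format is plain CSV (UTF-8, '.' decimal separator) with the
header ``subject_id, group, session, block, trial, role, endpoint_cm, score,
mistrial``.  Endpoints are printed at fixed 4-decimal precision; when a gain
function is supplied to the writer, scores and mistrial flags are recomputed
from the rounded endpoints so that ``score = gain(endpoint)`` holds exactly
for the values stored in the file.  Unknown extra columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .gain import GainFunction, gain

__all__ = ["read_trial_table", "write_trial_table", "write_block_summaries",
           "RunConfig"]

REQUIRED_COLUMNS = ["subject_id", "group", "session", "block", "trial",
                    "role", "endpoint_cm", "score", "mistrial"]
_DTYPES = {"subject_id": str, "group": str, "session": str, "role": str,
           "block": int, "trial": int, "endpoint_cm": float, "score": float}


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table, validating the schema (column order is free)."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    for col, typ in _DTYPES.items():
        if typ is str:
            continue
        try:
            df[col] = df[col].astype(typ)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise SchemaError(
                f"non-numeric value {df.loc[bad, col]!r} in column {col!r} "
                f"at data line {bad + 2} of {path}") from None
    df["mistrial"] = df["mistrial"].map(
        {"True": True, "False": False, "true": True, "false": False,
         "1": True, "0": False})
    if df["mistrial"].isna().any():
        raise SchemaError(f"non-boolean mistrial value in {path}")
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    return df[REQUIRED_COLUMNS + extras]


def write_trial_table(table: pd.DataFrame, path, gf: GainFunction | None = None,
                      config_hash: str | None = None, seed=None) -> None:
    """Write a trial table; endpoints at 4 decimals.

    With ``gf`` given, scores/mistrials are recomputed from the rounded
    endpoints (keeps the stored rows self-consistent).  ``config_hash`` and
    ``seed`` are embedded as a leading comment line for provenance.
    """
    df = table.copy()
    df["endpoint_cm"] = df["endpoint_cm"].round(4)
    if gf is not None:
        df["score"] = gain(df["endpoint_cm"].to_numpy(), gf)
        df["mistrial"] = ~((df["endpoint_cm"] > gf.dead_zone)
                           & (df["endpoint_cm"] <= gf.boundary))
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash is not None or seed is not None:
            fh.write(f"# reachrisk config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.4f")


def write_block_summaries(summaries: pd.DataFrame, path,
                          config_hash: str | None = None, seed=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash is not None or seed is not None:
            fh.write(f"# reachrisk config_hash={config_hash} seed={seed}\n")
        summaries.to_csv(fh, index=False, float_format="%.4f")


@dataclass
class RunConfig:
    """Fully serialisable description of one simulation/analysis run."""

    protocol: str = "exp1b"
    n_subjects: int = 8
    seed: int = 0
    gain: dict = field(default_factory=lambda: GainFunction().to_dict())
    agent: dict = field(default_factory=dict)       # SubjectModel overrides
    analysis: dict = field(default_factory=lambda: {
        "baseline_window": "baseline", "split_at": 0.0,
        "n_boot": 50_000, "tie_rule": "geq"})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    @property
    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def gain_function(self) -> GainFunction:
        return GainFunction.from_dict(self.gain)
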