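"""Trial CSV reading/writing and configuration files.

The interchange format is a plain UTF-8 CSV with columns ``subject``,
``speed_cond``, ``contrast_cond``, ``correct``, ``rt_s`` and, for
synthetic data, the latent ``origin`` column.  RTs are stored in seconds
at full float precision, condition codes are 1-5, ``correct`` is 0/1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import DesignParams, N_CONTRAST, N_SPEED
from .synthetic import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "TrialValidationError", "load_config", "load_design"]

_REQUIRED = ["subject", "speed_cond", "contrast_cond", "correct", "rt_s"]


class TrialValidationError(ValueError):
    """A trial file violates the format contract; names offending rows."""


def _validate(df: pd.DataFrame, origin_required: bool = False) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")

    def bad_rows(mask) -> str:
        rows = np.nonzero(mask.to_numpy())[0][:10] + 2  # 1-based + header line
        return ", ".join(map(str, rows))

    for col, lo, hi in (("speed_cond", 1, N_SPEED), ("contrast_cond", 1, N_CONTRAST)):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = ~vals.isin(range(lo, hi + 1))
        if mask.any():
            raise TrialValidationError(
                f"{col} outside {lo}..{hi} at file row(s) {bad_rows(mask)}"
            )
        df[col] = vals.astype(int)
    mask = ~pd.to_numeric(df["correct"], errors="coerce").isin((0, 1))
    if mask.any():
        raise TrialValidationError(f"correct not 0/1 at file row(s) {bad_rows(mask)}")
    df["correct"] = df["correct"].astype(int)
    rt = pd.to_numeric(df["rt_s"], errors="coerce")
    mask = ~(rt > 0)
    if mask.any():
        raise TrialValidationError(f"nonpositive rt_s at file row(s) {bad_rows(mask)}")
    df["rt_s"] = rt.astype(float)
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    return _validate(df)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (full float precision round trip)."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials.to_csv(path, index=False, columns=cols, float_format="%.17g")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file (returns an empty dict for an
    empty file)."""
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if out is None:
        return {}
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return out


def load_design(source: str | Path | dict | None) -> DesignParams:
    """Build DesignParams from a YAML file or dict with a ``design`` or
    top-level parameter mapping; None yields the canonical defaults."""
    from .params import canonical_design

    if source is None:
        return canonical_design()
    if not isinstance(source, dict):
        source = load_config(source)
    if "design" in source:
        source = source["design"]
    return DesignParams.from_dict(source)
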