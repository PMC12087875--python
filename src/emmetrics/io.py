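"""Cohort CSV reading/writing and the run configuration.

The on-disk cohort format is a UTF-8 CSV with decimal points and one row
per eye; the raw header is fixed (see :data:`~emmetrics.schema.RAW_COLUMNS`)
and derived files append the derived columns and, after classification, a
``subgroup`` column.  Writing uses the shortest-roundtrip float
representation, so write -> read is value-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DERIVED_COLUMNS, MEASURED_COLUMNS, RAW_COLUMNS, SUBGROUP_COLUMN

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "RunConfig", "config_hash"]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, rejecting malformed rows with their line numbers.

    A missing required column is fatal (the error names it); a cell that
    cannot be parsed as a number rejects only its row, which is logged with
    its 1-based file line number and recorded in
    ``DataFrame.attrs["rejected_lines"]``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in RAW_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} is missing required column {col!r}")

    numeric_cols = [c for c in df.columns
                    if c in MEASURED_COLUMNS or c in DERIVED_COLUMNS or c == "age_y"]
    bad = np.zeros(len(df), dtype=bool)
    out = {}
    for col in df.columns:
        if col in numeric_cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            failed = vals.isna() & (df[col] != "")
            if col != "age_y":  # only the optional age column may be empty
                failed |= df[col] == ""
            out[col] = vals
            bad |= failed.to_numpy()
        elif col == "eye_id":
            ids = pd.to_numeric(df[col], errors="coerce")
            out[col] = df[col] if ids.isna().any() else ids
        else:
            out[col] = df[col]
    res = pd.DataFrame(out)[list(df.columns)]
    rejected = [int(i) + 2 for i in np.flatnonzero(bad)]  # +2: header + 1-based
    for line in rejected:
        logger.warning("%s: rejecting malformed row at line %d", path.name, line)
    res = res[~bad].reset_index(drop=True)
    res.attrs["rejected_lines"] = rejected
    return res


def write_cohort(df: pd.DataFrame, path) -> Path:
    """Write a cohort CSV in canonical column order (raw, derived, subgroup)."""
    path = Path(path)
    cols = [c for c in RAW_COLUMNS if c in df.columns]
    cols += [c for c in DERIVED_COLUMNS if c in df.columns]
    if SUBGROUP_COLUMN in df.columns:
        cols.append(SUBGROUP_COLUMN)
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of a full reproduction run.

    Defaults are the published study conditions: a 2000-eye cohort, the
    reference bigaussian refraction parameters, 1000 mixture restarts,
    emmetropia at [-0.5, +0.5] D inclusive.
    """

    seed: int = 0
    n: int = 2000
    restarts: int = 1000
    mode: str = "refraction-first"
    input_csv: str | None = None
    out_dir: str = "emmetrics_run"
    epsilon_bracket: tuple[float, float] = (0.5, 5.0)
    emmetropia_bounds: tuple[float, float] = (-0.5, 0.5)
    se_fit_half_range: float = 10.0
    se_fit_bin_width: float = 1.0
    al_window: tuple[float, float] = (20.0, 27.0)
    uniqueness_parameters: tuple[str, ...] = (
        "SE_D", "P_c_D", "P_lb_D", "ACD_tot_mm", "LT_mm", "AL_mm")
    uniqueness_repeatabilities: tuple[float, ...] = (
        0.25, 0.12, 0.25, 0.009, 0.015, 0.019)
    uniqueness_limit_factor: float = 1.96
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical config JSON."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
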