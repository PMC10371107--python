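"""File formats and run configuration.

The interchange format is a long-format CSV trial table: one row per
recorded sample, with fixed column names and units (cm, seconds, Nm),
comma-separated, '.' decimal, UTF-8, mandatory header.  Models and reports
serialize to JSON.  An external-data loader maps third-party trajectory
tables onto the same schema through a layout descriptor, so the analysis
stage can run unchanged on real recordings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .controllers import DEFAULT_FORCE_WINDOW, DEFAULT_TORQUE_CAP
from .kinematics import DEFAULT_DT, DEFAULT_TD, ErrorSample
from .learner import SubjectResult, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "RunConfig",
    "records_to_table",
    "table_to_trials",
    "write_trials",
    "read_trials",
    "load_external_dataset",
    "config_hash",
]

logger = logging.getLogger("errorfields")

#: Column order and dtypes of the long-format trial table.
TRIAL_COLUMNS: dict[str, type] = {
    "subject_id": str,
    "group": str,
    "phase": str,
    "trial_index": int,
    "direction_id": int,
    "transformed": bool,
    "forces_on": bool,
    "t": float,            # seconds
    "x": float,            # cm
    "y": float,            # cm
    "extent_err": float,   # cm
    "perp_err": float,     # cm
    "torque_extent": float,  # Nm
    "torque_perp": float,    # Nm
}


class RunConfig(BaseModel):
    """Validated, fully-resolved run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    groups: list[str] = Field(default_factory=lambda: ["EF", "EA", "NULL"])
    n_per_group: int = 7
    n_baseline: int = 30
    n_intermittent: int = 50
    n_training: int = 70
    intermittent_fraction: float = 0.2
    dt: float = DEFAULT_DT
    td: float = DEFAULT_TD
    torque_cap: float = DEFAULT_TORQUE_CAP
    force_window: float = DEFAULT_FORCE_WINDOW
    sigma_floor: float = 0.05
    learning_rate_range: tuple[float, float] = (0.06, 0.16)
    noise_sd_range: tuple[float, float] = (0.2, 0.45)
    map_perturbation_sd: float = 0.05
    early_window: int = 10
    late_window: int = 10
    cv_repeats: int = 50
    cv_test_fraction: float = 0.2
    output_dir: str = "results"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.model_validate(doc or {})


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the resolved configuration, for log lines."""
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def records_to_table(
    records: Sequence[TrialRecord], subject_id: str = "S0", group: str = "NULL"
) -> pd.DataFrame:
    """Flatten trial records into the long-format trial table."""
    rows = {name: [] for name in TRIAL_COLUMNS}
    for rec in records:
        n = len(rec.trajectory)
        rows["subject_id"].extend([subject_id] * n)
        rows["group"].extend([group] * n)
        rows["phase"].extend([rec.phase] * n)
        rows["trial_index"].extend([rec.trial_index] * n)
        rows["direction_id"].extend([rec.direction_id] * n)
        rows["transformed"].extend([rec.transformed] * n)
        rows["forces_on"].extend([rec.forces_on] * n)
        rows["t"].extend(rec.trajectory.times.tolist())
        rows["x"].extend(rec.trajectory.points[:, 0].tolist())
        rows["y"].extend(rec.trajectory.points[:, 1].tolist())
        rows["extent_err"].extend([s.extent for s in rec.errors])
        rows["perp_err"].extend([s.perpendicular for s in rec.errors])
        rows["torque_extent"].extend([tq.extent for tq in rec.torques])
        rows["torque_perp"].extend([tq.perpendicular for tq in rec.torques])
    return pd.DataFrame(rows)


def subject_to_table(result: SubjectResult) -> pd.DataFrame:
    return records_to_table(result.records, result.subject_id, result.mode)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required column(s): {missing}")
    df = df[list(TRIAL_COLUMNS)].copy()
    for col, typ in TRIAL_COLUMNS.items():
        try:
            if typ is bool and df[col].dtype == object:
                df[col] = df[col].map(
                    {"True": True, "False": False, True: True, False: False}
                )
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} failed conversion to {typ.__name__}: {exc}")
    numeric = [c for c, t in TRIAL_COLUMNS.items() if t is float]
    bad = df[numeric].isna() | ~np.isfinite(df[numeric])
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col][bad[col]].index[0])
        raise ValueError(f"non-finite value in column {col!r} at row {row}")
    if len(df) and df.duplicated(subset=["subject_id", "trial_index", "t"]).any():
        raise ValueError("duplicate (subject_id, trial_index, t) rows")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the trial table as CSV (comma, '.' decimal, UTF-8, header)."""
    df = _validate_table(df)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read and schema-validate a trial-table CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    # keep_default_na: the control group's literal name "NULL" must survive
    df = pd.read_csv(path, encoding="utf-8", keep_default_na=False)
    return _validate_table(df)


def table_to_trials(df: pd.DataFrame, phase: str | None = None):
    """Reconstruct per-trial ErrorSample sequences from a trial table.

    Returns a list of (trial_index, direction_id, samples) in trial order;
    optionally restricted to one protocol phase.
    """
    if phase is not None:
        df = df[df["phase"] == phase]
    trials = []
    for (idx, d), g in df.groupby(["trial_index", "direction_id"], sort=True):
        samples = [
            ErrorSample(float(r.t), float(r.extent_err), float(r.perp_err), int(d))
            for r in g.itertuples()
        ]
        trials.append((int(idx), int(d), samples))
    return trials


#: Unit conversion factors into the table's native units.
_UNIT_FACTORS = {
    "cm": 1.0,
    "m": 100.0,
    "mm": 0.1,
    "s": 1.0,
    "ms": 1e-3,
    "Nm": 1.0,
}


def load_external_dataset(path, descriptor: Mapping) -> dict[str, pd.DataFrame]:
    """Load a third-party trajectory table into per-subject trial tables.

    ``descriptor`` maps the external layout onto the native schema:

    - ``columns``: {external column name -> trial-table column name}
    - ``units``: optional {trial-table column -> unit string} with
      conversion into cm/s/Nm (supported: cm, m, mm, s, ms, Nm)
    - ``defaults``: optional constant values for required columns the
      external table lacks (e.g. ``{"group": "EF", "forces_on": True}``)

    Unmapped external columns are logged and dropped.  Returns a dict
    keyed by subject_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"external dataset not found: {path}")
    raw = pd.read_csv(path)
    colmap = dict(descriptor.get("columns", {}))
    unknown_targets = [v for v in colmap.values() if v not in TRIAL_COLUMNS]
    if unknown_targets:
        raise ValueError(
            f"descriptor maps onto unknown column(s) {unknown_targets}; "
            f"valid targets: {list(TRIAL_COLUMNS)}"
        )
    missing_src = [c for c in colmap if c not in raw.columns]
    if missing_src:
        raise ValueError(
            f"descriptor references absent column(s) {missing_src}; "
            f"file contains: {list(raw.columns)}"
        )
    dropped = [c for c in raw.columns if c not in colmap]
    if dropped:
        logger.info("dropping unmapped columns: %s", dropped)
    df = raw[list(colmap)].rename(columns=colmap)

    for col, unit in dict(descriptor.get("units", {})).items():
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unsupported unit {unit!r} for column {col!r}")
        if col in df.columns:
            df[col] = df[col].astype(float) * _UNIT_FACTORS[unit]

    for col, value in dict(descriptor.get("defaults", {})).items():
        if col not in df.columns:
            df[col] = value

    still_missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if still_missing:
        raise ValueError(
            f"external layout leaves required column(s) unmapped: {still_missing}; "
            f"file contains: {list(raw.columns)}"
        )
    df = _validate_table(df)
    return {sid: g.reset_index(drop=True) for sid, g in df.groupby("subject_id")}
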