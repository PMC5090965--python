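"""File formats: trial-log, TAC and actigraphy CSV, NIfTI volumes, YAML config.

Every CSV written here carries a provenance header — ``#``-prefixed comment
lines recording the package version, the seed and a hash of the run
configuration — and every reader skips such lines, so round-trips are
lossless and re-running with the same configuration reproduces files byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import ActivitySeries
from .synth.behavior import TRIAL_LOG_COLUMNS
from .tac import TAC, FrameSchedule

__all__ = [
    "read_trial_log", "write_trial_log", "validate_trial_log",
    "read_tac", "write_tac",
    "read_volume", "write_volume",
    "read_actigraphy", "write_actigraphy",
    "RunConfig", "provenance_header",
]

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "concentration_kBq_per_mL"]
ACTIGRAPHY_COLUMNS = ["timestamp", "counts"]

_CHOICE_ENUM = {"left", "right"}


class SchemaError(ValueError):
    """A tabular input violated the documented schema."""


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    from . import __version__

    lines = [f"# petlearn {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        lines.append(f"# config_sha256={digest}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, config=None,
               float_format: str | None = "%.10g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        df.to_csv(fh, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------

def validate_trial_log(df: pd.DataFrame,
                       reward_maps: dict[str, dict[str, bool]] | None = None) -> None:
    """Raise :class:`SchemaError` (naming the first offending row) on violations.

    Checks the column set, choice-field enumerations (empty fields allowed
    only on aborted no-response rows), strictly increasing trial indices
    within each session and, when per-phase ``reward_maps`` are supplied,
    consistency of the ``rewarded`` flag with the map.
    """
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing columns: {missing}")
    chosen = df["chosen_stim"].fillna("").astype(str)
    side = df["chosen_side"].fillna("").astype(str)
    for i in df.index:
        if chosen[i] == "":
            if not df.loc[i, "aborted_session"]:
                raise SchemaError(f"row {i}: empty chosen_stim on a non-aborted row")
            continue
        if side[i] not in _CHOICE_ENUM:
            raise SchemaError(f"row {i}: chosen_side {side[i]!r} not in left/right")
        if chosen[i] not in (str(df.loc[i, "left_stim"]), str(df.loc[i, "right_stim"])):
            raise SchemaError(f"row {i}: chosen_stim not among the presented pair")
        if int(df.loc[i, "rewarded"]) not in (0, 1):
            raise SchemaError(f"row {i}: rewarded must be 0/1")
        if reward_maps is not None:
            phase = df.loc[i, "phase_label"]
            rmap = reward_maps.get(phase)
            if rmap is not None:
                expect = int(bool(rmap.get(chosen[i], False)))
                if expect != int(df.loc[i, "rewarded"]):
                    raise SchemaError(
                        f"row {i}: rewarded={df.loc[i, 'rewarded']} inconsistent "
                        f"with reward map of phase {phase!r}")
    for key, sess in df.groupby(["animal_id", "phase_label", "session_index"]):
        ti = sess["trial_index"].to_numpy()
        if not np.all(np.diff(ti) > 0):
            row = sess.index[np.flatnonzero(np.diff(ti) <= 0)[0] + 1]
            raise SchemaError(f"row {row}: non-increasing trial_index in session {key}")


def read_trial_log(path, reward_maps=None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#",
                     dtype={"animal_id": str, "group": str, "phase_label": str,
                            "task_kind": str},
                     keep_default_na=True)
    if df.empty and not df.columns.size:
        raise SchemaError(f"{path}: empty file without header")
    for c in ("left_stim", "right_stim", "chosen_stim", "chosen_side"):
        if c in df.columns:
            df[c] = df[c].fillna("").astype(str)
    validate_trial_log(df, reward_maps)
    return df


def write_trial_log(df: pd.DataFrame, path, seed=None, config=None) -> None:
    validate_trial_log(df)
    _write_csv(df[TRIAL_LOG_COLUMNS], path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# TACs
# ---------------------------------------------------------------------------

def read_tac(path) -> TAC:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: TAC file missing columns {missing}")
    start = df["frame_start_s"].to_numpy(dtype=float)
    dur = df["frame_duration_s"].to_numpy(dtype=float)
    conc = df["concentration_kBq_per_mL"].to_numpy(dtype=float)
    if np.any(dur <= 0):
        raise SchemaError(f"{path}: nonpositive frame duration")
    if not np.all(np.isfinite(conc)):
        raise SchemaError(f"{path}: non-finite concentration values")
    expected = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    if not np.allclose(start, expected, atol=1e-6):
        raise SchemaError(f"{path}: frames overlap or leave gaps")
    return TAC(FrameSchedule(dur), conc)


def write_tac(tac: TAC, path, seed=None, config=None) -> None:
    df = pd.DataFrame({
        "frame_start_s": tac.schedule.start_s,
        "frame_duration_s": tac.schedule.durations_s,
        "concentration_kBq_per_mL": tac.values,
    })
    _write_csv(df, path, seed=seed, config=config, float_format="%.10g")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path):
    import nibabel as nib

    return nib.load(str(path))


def write_volume(img, path) -> None:
    import nibabel as nib

    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------

def read_actigraphy(path, lights_on: float = 7.0, lights_off: float = 19.0) -> ActivitySeries:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ACTIGRAPHY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: actigraphy file missing columns {missing}")
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    counts = df["counts"].to_numpy()
    if np.any(counts < 0):
        raise SchemaError(f"{path}: negative counts")
    return ActivitySeries(times=times, counts=counts,
                          lights_on=lights_on, lights_off=lights_off)


def write_actigraphy(series: ActivitySeries, path, seed=None, config=None) -> None:
    df = pd.DataFrame({
        "timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": series.counts,
    })
    _write_csv(df, path, seed=seed, config=config, float_format=None)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated analysis configuration loaded from YAML."""

    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    criterion: float = 0.90
    session_size: int = 100
    alpha: float = 0.05
    alpha_bias: float = 0.01
    t_star: float = 30.0
    fwhm_mm: float = 2.0
    p_thresh: float = 0.05
    tail_n: int = 20
    groups: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r}: {p} does not exist")
        return cfg

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}
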