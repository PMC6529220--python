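"""File formats and run configuration.

Trial logs are comma-separated UTF-8 text with a header row, one row per
trial (schema :data:`visuohaptic.cohort.TRIAL_LOG_COLUMNS`); configurations
and reports are JSON (or YAML for configs). All writes are atomic
(write-to-temporary-then-rename), so interrupted runs never leave truncated
files.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .bayes import DEFAULT_SCALE
from .cohort import TRIAL_LOG_COLUMNS, CohortConfig
from .exceptions import ConfigError, DataError
from .physics import BondConfig


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_trial_log(path, log: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise DataError(f"trial log missing columns: {missing}")
    forces = log["pull_force_N"].dropna()
    if len(forces) and ((forces < 0).any() or (forces > 40).any()):
        raise DataError("pull forces outside [0, 40] N")
    atomic_write_text(path, log[TRIAL_LOG_COLUMNS].to_csv(index=False))


def read_trial_log(path) -> pd.DataFrame:
    log = pd.read_csv(
        path,
        dtype={
            "scene_code": "string",
            "pull_direction": "string",
            "trial_mode": "string",
            "choice": "string",
        },
        keep_default_na=True,
    )
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise DataError(f"trial log missing columns: {missing}")
    for col in ("first_pair", "second_pair", "correct"):
        log[col] = pd.to_numeric(log[col], errors="coerce").astype("Int64")
    for col in ("scene_code", "pull_direction", "trial_mode", "choice"):
        log[col] = log[col].fillna("")
    return log


def read_debriefing(path) -> pd.DataFrame:
    """Debriefing records: participant_id, noticed, n_correct_pairs,
    n_true_pairs (comma-separated with header)."""
    df = pd.read_csv(path)
    needed = {"participant_id", "noticed", "n_correct_pairs", "n_true_pairs"}
    if not needed.issubset(df.columns):
        raise DataError(f"debriefing file needs columns {sorted(needed)}")
    df["noticed"] = df["noticed"].astype(bool)
    return df


@dataclass
class RunConfig:
    """Seeds and analysis settings for one end-to-end run.

    Every stochastic stage has its own explicit seed: the cohort seed lives in
    ``cohort.seed``; ``design_seed`` drives design shuffles generated outside
    a simulation; ``analysis_seed`` drives the confidence-band sampler.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    design_seed: int = 0
    analysis_seed: int = 0
    n_band_samples: int = 100_000
    alpha: float = 0.05
    bf_scale: float = DEFAULT_SCALE

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_band_samples < 1:
            raise ConfigError("n_band_samples must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        bond = cohort.pop("bond", None) if isinstance(cohort, dict) else None
        if isinstance(cohort, dict):
            cohort = CohortConfig(
                **cohort, **({"bond": BondConfig(**bond)} if bond else {})
            )
        return cls(cohort=cohort, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix in (".yaml", ".yml"):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d or {})

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            atomic_write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            write_json(path, self.to_dict())


def design_table(trials) -> pd.DataFrame:
    """Export a pull/familiarity design as a delimited table."""
    from .scenes import FamiliarityTrial, PullTrial

    rows = []
    for i, t in enumerate(trials):
        if isinstance(t, PullTrial):
            rows.append(
                {
                    "trial_index": i,
                    "block": t.block_index,
                    "scene_code": t.scene.scene_code() if t.scene else t.configuration,
                    "pull_direction": t.direction,
                    "trial_mode": t.mode,
                    "breakage_force_N": t.breakage_force,
                    "first_pair": "",
                    "second_pair": "",
                }
            )
        elif isinstance(t, FamiliarityTrial):
            rows.append(
                {
                    "trial_index": i,
                    "block": t.block_index,
                    "scene_code": "",
                    "pull_direction": "",
                    "trial_mode": "",
                    "breakage_force_N": float("nan"),
                    "first_pair": t.first.pair_id,
                    "second_pair": t.second.pair_id,
                }
            )
        else:
            raise DataError(f"unknown trial type {type(t)}")
    return pd.DataFrame(rows)
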