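"""Readers, writers and run configuration.

Cases travel as long-format CSV tracks (``time_s, channel, value`` —
mirroring monitor track exports), cohorts as a manifest CSV, and derived
artifacts as JSON/TSV.  All writers are deterministic: no timestamps,
stable key order, shortest-repr floats, so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .simulate import DATASET_A_SIZES, Cohort, SpirometryRecord

logger = logging.getLogger("spirodesat")

__all__ = [
    "RunConfig",
    "read_case_csv",
    "write_case_csv",
    "read_manifest",
    "write_manifest",
    "write_json",
]

CHANNELS = ("PIP", "AWP", "VOL")


def write_case_csv(record: SpirometryRecord, path) -> None:
    """Write one case in long track format (time_s, channel, value)."""
    n = len(record)
    t = np.arange(n) / record.fs
    frames = [pd.DataFrame({"time_s": t, "channel": ch,
                            "value": record.channel(ch)}) for ch in CHANNELS]
    # %.17g guarantees exact float64 round-tripping
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_case_csv(path, fs: float = 15.0, case_id: str | None = None,
                  demographics=(0.0, 0.0, 0.0, 0.0),
                  label: int = 0) -> SpirometryRecord:
    """Read a long-format case CSV back into a record.

    Channels are aligned on the common time grid; rows with unparseable
    values are dropped (and counted in the log); a missing channel or a
    non-monotone time axis is a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError) as e:
        raise FormatError(f"{path}: {e}") from None
    required = {"time_s", "channel", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns "
                          f"{sorted(required - set(df.columns))}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
    bad = df["value"].isna() | df["time_s"].isna()
    if bad.any():
        logger.warning("%s: dropped %d malformed rows", path, int(bad.sum()))
        df = df[~bad]
    series = {}
    for ch in CHANNELS:
        sub = df[df["channel"] == ch]
        if sub.empty:
            raise FormatError(f"{path}: channel {ch} missing")
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise FormatError(f"{path}: non-monotone time axis in {ch}")
        series[ch] = sub["value"].to_numpy(dtype=float)
    n = min(len(v) for v in series.values())
    return SpirometryRecord(case_id=case_id or path.stem, fs=fs,
                            pip=series["PIP"][:n], awp=series["AWP"][:n],
                            vol=series["VOL"][:n],
                            demographics=tuple(demographics), label=int(label))


def write_manifest(cohort: Cohort, path) -> None:
    rows = []
    for rec, split in zip(cohort.records, cohort.split):
        sex, age, weight, height = rec.demographics
        rows.append({"case_id": rec.case_id, "sex": sex, "age": age,
                     "weight": weight, "height": height, "label": rec.label,
                     "split": split})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"case_id", "sex", "age", "weight", "height", "label", "split"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: manifest missing columns "
                          f"{sorted(required - set(df.columns))}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; one seed fans out everywhere."""

    seed: int = 0
    fs: float = 15.0
    n_normal: int = DATASET_A_SIZES[0]
    n_desat: int = DATASET_A_SIZES[1]
    simulate: dict = field(default_factory=dict)   # CaseProfile overrides
    selection_method: str = "sffs"                 # sffs|sbfs|filter|none
    selection_model: str = "knn"                   # wrapper scoring model
    filter_method: str = "anova_f"
    k_features: int = 10
    models: tuple = ("rf", "xgb", "lgbm", "knn", "svm")
    n_boot: int = 2000
    n_permutations: int = 1000
    write_cases: bool = False
    out_dir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["models"] = list(d["models"])
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go and
        whether raw cases are exported do not affect results)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("write_cases")
        d["models"] = list(d["models"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
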