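"""Trial-table CSV input/output and run configuration.

The interchange format is a UTF-8 comma-separated file with one row per
trial, session order preserved, header:

    participant,condition,block_index,trial_index,soa_ms,congruency,
    prime_dir,target_dir,response,rt_ms,correct,excluded

Times are milliseconds in files (seconds are used only inside the models);
an empty rt field means a missing RT (time-out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SOA_STEP_MS, TRIAL_COLUMNS


class TrialTableError(ValueError):
    """Malformed trial table; the message carries the offending line numbers."""


def write_trials(dataset: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (numeric RTs at 6 significant digits)."""
    out = dataset[TRIAL_COLUMNS].copy()
    out["rt_ms"] = out["rt_ms"].map(
        lambda v: "" if pd.isna(v) else format(float(v), ".6g")
    )
    out["correct"] = out["correct"].map(
        lambda v: "" if v is None or v != v else str(bool(v))
    )
    out["response"] = out["response"].fillna("none")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV; errors report line numbers."""
    df = pd.read_csv(
        path,
        dtype={
            "participant": str,
            "condition": str,
            "congruency": str,
            "prime_dir": str,
            "target_dir": str,
            "response": str,
        },
        keep_default_na=True,
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    bad_lines = []
    cong_ok = df["congruency"].isin(["C", "IC"])
    soa = df["soa_ms"].to_numpy()
    soa_ok = (soa >= 0) & (soa % SOA_STEP_MS == 0)
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    rt_ok = df["rt_ms"].isna() | (rt > 0)
    for i in np.flatnonzero(~(cong_ok & soa_ok & rt_ok)):
        bad_lines.append(i + 2)  # header is line 1
    if bad_lines:
        raise TrialTableError(f"malformed trial rows at lines {bad_lines}")
    df["rt_ms"] = rt
    df["correct"] = df["correct"].map(
        lambda v: None if pd.isna(v) else str(v).lower() == "true"
    )
    df["excluded"] = df["excluded"].map(lambda v: str(v).lower() == "true")
    df["response"] = df["response"].replace({"none": None})
    return df.sort_values(["participant", "condition", "trial_index"]).reset_index(
        drop=True
    )


_CONFIG_DEFAULTS = {
    "design": "huang_masked",
    "model": "otem_additive",
    "f": 3.3,
    "weber_k": 0.13,
    "bounds": {},
    "n_restarts": 10,
    "n_perm": 1000,
    "n_sims": 100,
    "seed": 0,
    "output_dir": "otem_out",
}


@dataclass
class RunConfig:
    """Validated run configuration (JSON document of known keys).

    Unknown keys are rejected; missing keys get explicit defaults so every
    loaded config is complete, including all seeds.
    """

    design: str = "huang_masked"
    model: str = "otem_additive"
    f: float = 3.3
    weber_k: float = 0.13
    bounds: dict = field(default_factory=dict)
    n_restarts: int = 10
    n_perm: int = 1000
    n_sims: int = 100
    seed: int = 0
    output_dir: str = "otem_out"

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{**_CONFIG_DEFAULTS, **raw})

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
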