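"""Experiment configuration and run manifests.

One configuration drives a whole multi-size experiment, mirroring the
per-size ensemble design of the transient-lifetime studies: for each
domain size an ensemble of seeded initial conditions is generated,
episodes are run to self-termination (or a censoring cap), and the
survival/escape-rate and across-size scaling fits are applied.  Every
stochastic stage derives its seed deterministically from the base seed,
the stage label and the episode index, so any artifact can be traced to
(config hash, base seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = ["ExperimentConfig", "RunManifest", "stage_seed"]


def stage_seed(base_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class ExperimentConfig:
    """Settings of one multi-size transient-chaos experiment."""

    model: str = "bocf"                    # bocf | tnnp
    parameter_set: Optional[str] = None    # parameter file set/variant label
    domain_lengths: Tuple[float, ...] = (60.0, 80.0, 100.0)   # L in mm
    h: Optional[float] = None              # grid spacing; model default if None
    dt: Optional[float] = None             # time step; model default if None
    ensemble_size: int = 10                # ICs per domain size
    t_max: float = 10.0                    # censoring cap per episode (s)
    sample_interval: float = 0.01          # observer interval (s)
    confirm_window: float = 0.2            # quiet window for termination (s)
    min_spirals: int = 2                   # IC acceptance threshold
    settle_time: float = 1.0               # protocol settling (s)
    fit_threshold_fraction: float = 0.10
    T_obs: float = 80.0                    # time-average window (s)
    base_seed: int = 0
    output_root: str = "runs"
    write_snapshots: bool = False

    def __post_init__(self):
        if self.model not in ("bocf", "tnnp"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.ensemble_size < 1 or self.t_max <= 0:
            raise ValueError("ensemble_size >= 1 and t_max > 0 required")
        if any(L <= 0 for L in self.domain_lengths):
            raise ValueError("domain lengths must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["domain_lengths"] = tuple(doc.get("domain_lengths",
                                              cls.domain_lengths))
        return cls(**doc)

    def to_dict(self) -> Dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


MANIFEST_COLUMNS = ["episode_id", "seed", "L_mm", "A_mm2", "lifetime_s",
                    "status", "n_spiral_initial", "series_path",
                    "snapshot_path"]


class RunManifest:
    """Append-only per-episode bookkeeping behind a CSV file."""

    def __init__(self, path, config: ExperimentConfig):
        self.path = Path(path)
        self.config = config
        if self.path.exists():
            self.df = pd.read_csv(self.path)
            missing = set(MANIFEST_COLUMNS) - set(self.df.columns)
            if missing:
                raise ValueError(f"manifest at {path} lacks columns {missing}")
        else:
            self.df = pd.DataFrame(columns=MANIFEST_COLUMNS)

    def has_episode(self, episode_id: str) -> bool:
        return bool((self.df["episode_id"] == episode_id).any())

    def append(self, row: Dict):
        if self.has_episode(row["episode_id"]):
            raise ValueError(f"episode {row['episode_id']} already recorded")
        new = pd.DataFrame([row])
        self.df = (new if self.df.empty
                   else pd.concat([self.df, new], ignore_index=True))
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(self.path, index=False)

    def episodes(self) -> pd.DataFrame:
        return self.df.copy()
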