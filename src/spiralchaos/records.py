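"""Episode-level result containers shared by the simulator and the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TERMINATED = "terminated"
CENSORED = "censored"
BLOWUP = "blowup"


@dataclass
class EpisodeRecord:
    """Outcome of one simulated episode.

    ``lifetime`` is the time of the last downward crossing of the
    excitation threshold for terminated episodes, the censoring time for
    censored episodes, and the time of failure for numerical blow-ups
    (lifetime then censored in the statistical sense).
    """

    lifetime: float
    status: str                       # terminated | censored | blowup
    spiral_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spiral_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    seed: Optional[int] = None
    area: Optional[float] = None      # mm^2

    def __post_init__(self):
        if self.lifetime < 0:
            raise ValueError("lifetime must be >= 0")
        if self.status not in (TERMINATED, CENSORED, BLOWUP):
            raise ValueError(f"unknown status {self.status!r}")
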