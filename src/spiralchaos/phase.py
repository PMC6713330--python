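"""Phase fields and phase-singularity (spiral-tip) detection.

Two-step protocol: (1) assign every grid point a phase angle theta from a
two-dimensional projection of the local dynamics; (2) locate phase
singularities as the points where the closed line integral of grad theta
around an elementary lattice plaquette equals +-2 pi (winding number
+-1, the topological charge / chirality of the spiral tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .integrator import TissueState

__all__ = [
    "PhaseField", "PhaseSingularity", "PhaseProjection",
    "compute_phase", "detect_phase_singularities", "count_spirals",
    "boundary_winding", "SpiralCounter",
]


@dataclass
class PhaseField:
    """Angles in (-pi, pi] on the grid at time t."""

    theta: np.ndarray
    h: float = 1.0            # mm, grid spacing (for reporting tip positions)
    t: float = 0.0

    def __post_init__(self):
        if np.any(self.theta <= -np.pi) or np.any(self.theta > np.pi):
            raise ValueError("phase values must lie in (-pi, pi]")


@dataclass(frozen=True)
class PhaseSingularity:
    """Detected spiral tip: position in mm, topological charge +-1."""

    x: float
    y: float
    charge: int
    t: float = 0.0

    def __post_init__(self):
        if abs(self.charge) != 1:
            raise ValueError("charge must be +-1")


@dataclass(frozen=True)
class PhaseProjection:
    """Which two observables span the phase plane, and the origin.

    BOCF default: (u, v) about (0.3, 0.5).  For TNNP a time-delay
    embedding of V_m is the generic choice; ``obs2`` then names the
    delayed copy which the caller must supply (see :class:`SpiralCounter`).
    """

    obs1: str = "u"
    obs2: str = "v"
    origin: Tuple[float, float] = (0.3, 0.5)

    @classmethod
    def bocf_default(cls) -> "PhaseProjection":
        return cls("u", "v", (0.3, 0.5))

    @classmethod
    def tnnp_default(cls) -> "PhaseProjection":
        return cls("V", "V_delayed", (-40.0, -40.0))


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.mod(-a + np.pi, 2.0 * np.pi)
    return np.pi - out


def compute_phase(state: TissueState, projection: Optional[PhaseProjection] = None,
                  delayed: Optional[np.ndarray] = None) -> PhaseField:
    """theta = angle of (obs1 - o1, obs2 - o2) at every grid point.

    ``delayed`` supplies the second observable when the projection uses a
    time-delayed copy that is not part of the instantaneous state.
    Points where both components vanish get theta = 0.
    """
    if projection is None:
        projection = (PhaseProjection.bocf_default() if state.model == "bocf"
                      else PhaseProjection.tnnp_default())
    a = getattr(state.cell, projection.obs1) - projection.origin[0]
    if projection.obs2.endswith("_delayed"):
        if delayed is None:
            raise ValueError("projection uses a delayed observable; "
                             "pass the delayed field")
        b = delayed - projection.origin[1]
    else:
        b = getattr(state.cell, projection.obs2) - projection.origin[1]
    theta = np.arctan2(b, a)
    theta = np.where((a == 0) & (b == 0), 0.0, theta)
    theta = np.where(theta <= -np.pi, np.pi, theta)
    return PhaseField(theta=theta, h=state.grid.h, t=state.t)


def _plaquette_winding(theta: np.ndarray) -> np.ndarray:
    """Winding sum (in units of 2 pi) around every elementary 2x2 plaquette.

    The counter-clockwise loop (i,j) -> (i,j+1) -> (i+1,j+1) -> (i+1,j)
    accumulates the wrapped phase differences; the result is integer-
    valued up to rounding because each difference lies in (-pi, pi].
    """
    d1 = _wrap(theta[:-1, 1:] - theta[:-1, :-1])
    d2 = _wrap(theta[1:, 1:] - theta[:-1, 1:])
    d3 = _wrap(theta[1:, :-1] - theta[1:, 1:])
    d4 = _wrap(theta[:-1, :-1] - theta[1:, :-1])
    return (d1 + d2 + d3 + d4) / (2.0 * np.pi)


def detect_phase_singularities(phase: PhaseField, *,
                               margin: int = 0) -> List[PhaseSingularity]:
    """Phase singularities from elementary-plaquette winding numbers.

    A plaquette with |winding| > 1/2 carries charge sign(winding);
    adjacent flagged plaquettes of equal charge (8-connectivity) are
    merged into one tip at their centroid.  ``margin`` excludes
    plaquettes within that many cells of the boundary (default 0: the
    whole domain is evaluated).
    """
    w = _plaquette_winding(phase.theta)
    if margin > 0:
        mask = np.zeros_like(w, dtype=bool)
        mask[margin:w.shape[0] - margin, margin:w.shape[1] - margin] = True
    else:
        mask = np.ones_like(w, dtype=bool)

    tips: List[PhaseSingularity] = []
    for charge in (1, -1):
        flagged = mask & (w * charge > 0.5)
        if not np.any(flagged):
            continue
        labels, n = ndimage.label(flagged, structure=np.ones((3, 3), dtype=int))
        centroids = ndimage.center_of_mass(flagged, labels, range(1, n + 1))
        for cy, cx in centroids:
            # plaquette (i, j) is centred at grid position (j + 0.5, i + 0.5)
            tips.append(PhaseSingularity(
                x=(cx + 0.5) * phase.h, y=(cy + 0.5) * phase.h,
                charge=charge, t=phase.t))
    return tips


def boundary_winding(phase: PhaseField) -> int:
    """Total winding number along the outer boundary of the domain.

    Equals the sum of all enclosed topological charges (charge
    conservation diagnostic).
    """
    th = phase.theta
    loop = np.concatenate([
        th[0, :],                # bottom row, left -> right
        th[1:, -1],              # right column, upward
        th[-1, -2::-1],          # top row, right -> left
        th[-2:0:-1, 0],          # left column, downward
    ])
    d = _wrap(np.diff(np.concatenate([loop, loop[:1]])))
    return int(np.round(d.sum() / (2.0 * np.pi)))


def count_spirals(state: TissueState, projection: Optional[PhaseProjection] = None,
                  *, delayed: Optional[np.ndarray] = None,
                  margin: int = 0) -> int:
    """N_spiral: the number of phase singularities in the state."""
    phase = compute_phase(state, projection, delayed=delayed)
    return len(detect_phase_singularities(phase, margin=margin))


class SpiralCounter:
    """Observer for :func:`spiralchaos.integrator.run_episode`.

    Counts phase singularities at every observer call and stores the
    (t, N_spiral) series.  For delay-embedded projections it keeps a ring
    buffer of the potential so the delayed copy is available; until the
    buffer fills, the current field doubles as the delayed one (phase is
    then degenerate and counts are recorded as 0).
    """

    def __init__(self, projection: Optional[PhaseProjection] = None,
                 margin: int = 0, delay_samples: int = 1):
        self.projection = projection
        self.margin = margin
        self.delay_samples = delay_samples
        self._buffer: List[np.ndarray] = []
        self.times: List[float] = []
        self.counts: List[int] = []

    def __call__(self, state: TissueState):
        proj = self.projection
        if proj is None:
            proj = (PhaseProjection.bocf_default() if state.model == "bocf"
                    else PhaseProjection.tnnp_default())
        delayed = None
        if proj.obs2.endswith("_delayed"):
            self._buffer.append(state.potential.copy())
            if len(self._buffer) > self.delay_samples + 1:
                self._buffer.pop(0)
            if len(self._buffer) <= self.delay_samples:
                self.times.append(state.t)
                self.counts.append(0)
                return
            delayed = self._buffer[0]
        n = count_spirals(state, proj, delayed=delayed, margin=self.margin)
        self.times.append(state.t)
        self.counts.append(n)

    def series(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.counts, dtype=int)
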