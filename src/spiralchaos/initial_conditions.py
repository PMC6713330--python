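"""Multi-spiral initial conditions from randomized stimulation protocols.

An initial condition is manufactured by driving the resting tissue with
a sequence of spatially distributed local stimuli: a first plane-wave
excitation along one edge followed by several randomly placed point
stimuli timed into the repolarization tail of the preceding activity
(cross-field-style spiral induction), then a settling interval.  The
end state is accepted only if it contains at least ``min_spirals`` phase
singularities; otherwise the protocol is resampled with a deterministic
sub-seed, up to a retry cap.

Every knob is exposed so the scheme can be tuned without code changes;
the specific geometry/timing here is standard induction practice, not a
reconstruction of any particular published protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .grid import Grid
from .integrator import NumericsConfig, TissueState, step
from .phase import PhaseProjection, count_spirals

__all__ = ["Stimulus", "StimulusProtocol", "ProtocolKnobs",
           "sample_protocol", "make_initial_condition",
           "planted_spiral_pair_state", "randomized_spiral_state"]


@dataclass(frozen=True)
class Stimulus:
    """One local stimulus: disc of given radius, constant current pulse."""

    x: float            # mm
    y: float            # mm
    radius: float       # mm
    amplitude: float    # model current units (1/s for BOCF, pA/pF for TNNP)
    onset: float        # s
    duration: float     # s


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus sequence plus the seed that generated it."""

    stimuli: Tuple[Stimulus, ...]
    seed: int
    settle_time: float = 2.0     # s of stimulus-free relaxation at the end

    def __post_init__(self):
        onsets = [s.onset for s in self.stimuli]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be nondecreasing")
        if any(s.radius <= 0 for s in self.stimuli):
            raise ValueError("stimulus radii must be > 0")

    @property
    def total_time(self) -> float:
        if not self.stimuli:
            return self.settle_time
        last = self.stimuli[-1]
        return last.onset + last.duration + self.settle_time

    def current_field(self, grid: Grid, t: float) -> Optional[np.ndarray]:
        """Summed stimulation current at time t, or None if quiescent."""
        active = [s for s in self.stimuli
                  if s.onset <= t < s.onset + s.duration]
        if not active:
            return None
        ys, xs = np.meshgrid(np.arange(grid.n_y) * grid.h,
                             np.arange(grid.n_x) * grid.h, indexing="ij")
        out = np.zeros(grid.shape)
        for s in active:
            mask = (xs - s.x) ** 2 + (ys - s.y) ** 2 <= s.radius ** 2
            out[mask] += s.amplitude
        return out


@dataclass(frozen=True)
class ProtocolKnobs:
    """Tunable parameters of the induction scheme.

    Defaults are sized for the BOCF model (dimensionless currents,
    action-potential duration ~0.3 s); the onset gaps aim the point
    stimuli into the repolarization tails of earlier waves.
    """

    n_point_stimuli: Tuple[int, int] = (3, 5)    # inclusive range
    # stimulus discs must straddle a length of the recovery front
    # commensurate with the wavelength to leave free ends that curl;
    # None -> 0.2 * min(L_x, L_y), floored at 6 mm
    point_radius: Optional[float] = None
    point_amplitude: float = -150.0              # 1/s (J_stim < 0 depolarizes)
    point_duration: float = 0.01                 # s
    plane_width: float = 4.0                     # mm, S1 strip along x = 0
    plane_amplitude: float = -150.0
    plane_duration: float = 0.01
    # the S1 wave sweeps +x, so the tissue at x repolarizes near
    # t = x/cv_estimate + apd_estimate; point stimuli are aimed at that
    # moment (plus jitter) to straddle the recovery front — the
    # vulnerable window where a crescent wave with free ends forms
    cv_estimate: float = 535.0                   # mm/s, BOCF plane-wave speed
    apd_estimate: float = 0.30                   # s, action-potential duration
    onset_jitter: Tuple[float, float] = (-0.04, 0.16)  # s around the target
    min_onset_spacing: float = 0.08              # s; closer stimuli are dropped
    settle_time: float = 2.0                     # s
    min_spirals: int = 4
    max_attempts: int = 10


def _subseed(seed: int, attempt: int) -> int:
    """Deterministic sub-seed for retry ``attempt`` (0 = first try)."""
    return int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0]
               % (2 ** 31))


def sample_protocol(grid: Grid, seed: int,
                    knobs: ProtocolKnobs = ProtocolKnobs()) -> StimulusProtocol:
    """Draw a stimulation protocol; deterministic in (seed, knobs, grid)."""
    radius = knobs.point_radius
    if radius is None:
        radius = max(0.2 * min(grid.L_x, grid.L_y), 6.0)
    if grid.L_x <= 2 * radius or grid.L_y <= 2 * radius:
        raise ValueError("domain too small to place a point stimulus")
    rng = np.random.default_rng(seed)
    # S1 "plane" stimulus: a row of overlapping discs spanning the left edge
    stimuli: List[Stimulus] = []
    r = knobs.plane_width
    n_discs = int(np.ceil(grid.L_y / r)) + 1
    for k in range(n_discs):
        stimuli.append(Stimulus(
            x=0.0, y=k * r, radius=r, amplitude=knobs.plane_amplitude,
            onset=0.0, duration=knobs.plane_duration))
    n_pts = int(rng.integers(knobs.n_point_stimuli[0],
                             knobs.n_point_stimuli[1] + 1))
    pts = []
    for _ in range(n_pts):
        x = float(rng.uniform(radius, grid.L_x - radius))
        y = float(rng.uniform(radius, grid.L_y - radius))
        onset = (x / knobs.cv_estimate + knobs.apd_estimate
                 + float(rng.uniform(*knobs.onset_jitter)))
        pts.append(Stimulus(
            x=x, y=y, radius=radius,
            amplitude=knobs.point_amplitude,
            onset=max(onset, knobs.plane_duration),
            duration=knobs.point_duration))
    # near-simultaneous stimuli flood the medium with one synchronised
    # wave that wipes out freshly created rotors; enforce a minimum
    # spacing by deterministic thinning
    kept = []
    for s in sorted(pts, key=lambda s: s.onset):
        if not kept or s.onset - kept[-1].onset >= knobs.min_onset_spacing:
            kept.append(s)
    stimuli.extend(kept)
    return StimulusProtocol(stimuli=tuple(stimuli), seed=seed,
                            settle_time=knobs.settle_time)


def make_initial_condition(grid: Grid, params, cfg: NumericsConfig, seed: int,
                           knobs: ProtocolKnobs = ProtocolKnobs(), *,
                           model: str = "bocf",
                           projection: Optional[PhaseProjection] = None,
                           return_info: bool = False):
    """Simulate a protocol from rest and return an accepted multi-spiral state.

    Retries with deterministic sub-seeds until the end state holds at
    least ``knobs.min_spirals`` phase singularities.  The returned
    state's clock is reset to t = 0 (episode start).
    """
    last_counts = []
    for attempt in range(knobs.max_attempts):
        protocol = sample_protocol(grid, _subseed(seed, attempt), knobs)
        state = TissueState.resting(model, grid, params)
        n_steps = int(round(protocol.total_time / cfg.dt))
        for _ in range(n_steps):
            stim = protocol.current_field(grid, state.t)
            step(state, params, cfg, stimulus=stim, check_stability=False)
        n = count_spirals(state, projection)
        last_counts.append(n)
        if n >= knobs.min_spirals:
            state.t = 0.0
            if return_info:
                return state, {"seed": seed, "attempts": attempt + 1,
                               "n_spiral": n, "protocol": protocol}
            return state
    raise RuntimeError(
        f"no protocol produced >= {knobs.min_spirals} spirals in "
        f"{knobs.max_attempts} attempts (seed {seed}; counts {last_counts}); "
        f"consider more/stronger point stimuli or a larger domain")


def randomized_spiral_state(grid: Grid, params, cfg: NumericsConfig,
                            seed: int, *, model: str = "bocf",
                            extra_stimuli: int = 0) -> TissueState:
    """Seeded multi-spiral state via a randomized cut-a-wave construction.

    Much cheaper than a full stimulation protocol (a fraction of a second
    of simulated time): the cut fraction and the surviving band of the
    wave are drawn from the seed, giving statistically distinct spiral
    configurations per seed.  ``extra_stimuli`` optional point stimuli
    are fired shortly after the cut to raise the spiral count.
    """
    rng = np.random.default_rng(seed)
    cut = float(rng.uniform(0.45, 0.70))
    b0 = float(rng.uniform(0.10, 0.35))
    b1 = b0 + float(rng.uniform(0.30, 0.50))
    state = planted_spiral_pair_state(grid, params, cfg, model=model,
                                      cut_fraction=cut, band=(b0, min(b1, 0.95)))
    for _ in range(extra_stimuli):
        # brief point stimulus into the curling wave's neighbourhood
        n_settle = int(round(float(rng.uniform(0.08, 0.2)) / cfg.dt))
        for _ in range(n_settle):
            step(state, params, cfg, check_stability=False)
        ys, xs = np.meshgrid(np.arange(grid.n_y) * grid.h,
                             np.arange(grid.n_x) * grid.h, indexing="ij")
        cx = float(rng.uniform(0.2, 0.8)) * grid.L_x
        cy = float(rng.uniform(0.2, 0.8)) * grid.L_y
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= rng.uniform(5.0, 10.0) ** 2
        stim_field = np.where(mask, -150.0, 0.0)
        for _ in range(int(round(0.01 / cfg.dt))):
            step(state, params, cfg, stimulus=stim_field,
                 check_stability=False)
    state.t = 0.0
    return state


def planted_spiral_pair_state(grid: Grid, params, cfg: NumericsConfig, *,
                              model: str = "bocf",
                              cut_fraction: float = 0.55,
                              band: Tuple[float, float] = (0.25, 0.75)
                              ) -> TissueState:
    """Deterministic spiral pair via the cut-a-wave construction.

    A plane wave is launched from the left edge; when its front passes
    ``cut_fraction`` of the domain width the excited variable is reset
    outside the horizontal band ``band`` (fractions of L_y), leaving a
    wave segment with two free ends that curl into a counter-rotating
    spiral pair.
    """
    if model != "bocf":
        raise NotImplementedError("the cut-a-wave helper supports BOCF only")
    state = TissueState.resting(model, grid, params)
    stim = np.zeros(grid.shape)
    stim[:, : max(2, int(3.0 / grid.h))] = -150.0
    thr = 0.5 * (params.theta_v + params.u_u)     # "excited" level for tracking
    stim_steps = int(round(0.01 / cfg.dt))
    x_cut = cut_fraction * grid.L_x
    max_steps = int(round(2.0 / cfg.dt))
    for i in range(max_steps):
        step(state, params, cfg,
             stimulus=stim if i < stim_steps else None, check_stability=False)
        if i % 50 == 0:
            excited = state.cell.u > thr
            if excited.any():
                front_x = np.max(np.nonzero(excited.any(axis=0))[0]) * grid.h
                if front_x >= x_cut:
                    break
    else:
        raise RuntimeError("plane wave never reached the cut position")
    lo = int(band[0] * grid.n_y)
    hi = int(band[1] * grid.n_y)
    mask = np.ones(grid.shape, dtype=bool)
    mask[lo:hi, :] = False
    state.cell.u = np.where(mask, 0.0, state.cell.u)
    state.t = 0.0
    return state
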