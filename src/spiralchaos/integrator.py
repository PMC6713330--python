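"""2-D monodomain integrator.

Advances the reaction-diffusion equation

    dV/dt = div(D grad V) - (I_ion + I_stim)/C_m

on a uniform square grid with no-flux boundaries.  The Laplacian uses
the isotropic nine-point stencil; potential and concentration variables
take a first-order explicit Euler step, gating variables a first-order
Rush-Larsen step (exact exponential update with rates frozen at the
start-of-step potential).

Time is measured in seconds throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence

import numpy as np

from .grid import Grid
from .models.bocf import BOCFParams, BOCFState, bocf_currents, bocf_gating_rhs
from .models.tnnp import TNNP_GATES, TNNPParams, TNNPState, tnnp_rhs
from .records import BLOWUP, CENSORED, TERMINATED, EpisodeRecord

__all__ = ["NumericsConfig", "TissueState", "laplacian9", "step",
           "run_episode", "StabilityError"]


class StabilityError(ValueError):
    """Time step violates the explicit-Euler diffusion stability guard."""


@dataclass(frozen=True)
class NumericsConfig:
    """Discretisation settings.

    The stability guard refuses dt > stability_factor * h^2 / D; with the
    conservative factor 0.25 an explicit-Euler diffusion blow-up cannot be
    mistaken for physiological self-termination.
    """

    dt: float                       # s
    h: float                        # mm
    laplacian_stencil: str = "nine_point"
    boundary: str = "no_flux"
    stability_factor: float = 0.25

    def __post_init__(self):
        if self.dt <= 0 or self.h <= 0:
            raise ValueError("dt and h must be > 0")
        if self.laplacian_stencil != "nine_point":
            raise ValueError("only the nine-point stencil is supported")
        if self.boundary != "no_flux":
            raise ValueError("only no-flux boundaries are supported")

    @classmethod
    def bocf_defaults(cls) -> "NumericsConfig":
        return cls(dt=1e-4, h=1.0)

    @classmethod
    def tnnp_defaults(cls) -> "NumericsConfig":
        return cls(dt=2e-5, h=0.2)

    def check_stability(self, D: float):
        limit = self.stability_factor * self.h ** 2 / D
        if self.dt > limit:
            raise StabilityError(
                f"dt = {self.dt:g} s exceeds the diffusion stability guard "
                f"{limit:g} s (h = {self.h:g} mm, D = {D:g} mm^2/s)")


@dataclass
class TissueState:
    """All model state variables on a 2-D grid plus the simulation clock."""

    model: str                      # "bocf" | "tnnp"
    grid: Grid
    cell: object                    # BOCFState or TNNPState with 2-D arrays
    t: float = 0.0

    def __post_init__(self):
        if self.model not in ("bocf", "tnnp"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        for name in self._field_names():
            a = getattr(self.cell, name)
            if a.shape != self.grid.shape:
                raise ValueError(
                    f"field '{name}' shape {a.shape} != grid {self.grid.shape}")

    def _field_names(self):
        return ("u", "v", "w", "s") if self.model == "bocf" else TNNPState.VAR_NAMES

    @classmethod
    def resting(cls, model: str, grid: Grid, params=None) -> "TissueState":
        if model == "bocf":
            return cls("bocf", grid, BOCFState.resting(grid.shape, params))
        return cls("tnnp", grid, TNNPState.resting(grid.shape))

    @property
    def potential(self) -> np.ndarray:
        """The propagating variable: u for BOCF, V_m for TNNP."""
        return self.cell.u if self.model == "bocf" else self.cell.V

    def copy(self) -> "TissueState":
        return TissueState(self.model, self.grid, self.cell.copy(), self.t)

    def is_finite(self) -> bool:
        return all(np.all(np.isfinite(getattr(self.cell, n)))
                   for n in self._field_names())


# isotropic nine-point stencil: (1/6h^2) [[1,4,1],[4,-20,4],[1,4,1]],
# exact for quadratics and with O(h^2) isotropic error.
def laplacian9(f: np.ndarray, h: float, *, check_finite: bool = False) -> np.ndarray:
    """Nine-point Laplacian with no-flux (mirror-across-face) boundaries.

    Ghost cells replicate the boundary value, i.e. mirror reflection
    across the domain face half a cell outside the outermost nodes; this
    makes the discrete integral of the operator vanish exactly, so
    diffusion conserves total mass to rounding.
    """
    if f.ndim != 2 or min(f.shape) < 3:
        raise ValueError("field must be 2-D, at least 3x3")
    if check_finite and not np.all(np.isfinite(f)):
        raise ValueError("non-finite entries in field")
    g = np.pad(f, 1, mode="edge")
    c = g[1:-1, 1:-1]
    edges = g[:-2, 1:-1] + g[2:, 1:-1] + g[1:-1, :-2] + g[1:-1, 2:]
    corners = g[:-2, :-2] + g[:-2, 2:] + g[2:, :-2] + g[2:, 2:]
    return (4.0 * edges + corners - 20.0 * c) / (6.0 * h * h)


def step(state: TissueState, params, cfg: NumericsConfig,
         stimulus: Optional[np.ndarray] = None, *,
         diffusion_only: bool = False, check_stability: bool = True
         ) -> TissueState:
    """Advance one time step of length cfg.dt (in place; returns state).

    ``stimulus`` is the (rescaled) stimulation current field: J_stim in
    1/s for BOCF, I_stim in pA/pF for TNNP.  ``diffusion_only`` switches
    the reaction terms off (used by conservation tests).
    """
    if check_stability:
        cfg.check_stability(params.D)
    if state.model == "bocf":
        _step_bocf(state, params, cfg, stimulus, diffusion_only)
    else:
        _step_tnnp(state, params, cfg, stimulus, diffusion_only)
    state.t += cfg.dt
    return state


def _step_bocf(state: TissueState, p: BOCFParams, cfg: NumericsConfig,
               stimulus, diffusion_only):
    c = state.cell
    dt = cfg.dt
    lap = laplacian9(c.u, cfg.h)
    if diffusion_only:
        c.u = c.u + dt * p.D * lap
        return
    J_fi, J_so, J_si = bocf_currents(c, p, validate=False)
    reaction = J_fi + J_so + J_si
    if stimulus is not None:
        reaction = reaction + stimulus
    _, (v_inf, tau_v, w_inf, tau_w, s_inf, tau_s) = bocf_gating_rhs(
        c, p, validate=False)
    c.u = c.u + dt * (p.D * lap - reaction)
    # Rush-Larsen: exact solution of the frozen-rate gate ODE
    c.v = v_inf - (v_inf - c.v) * np.exp(-dt / tau_v)
    c.w = w_inf - (w_inf - c.w) * np.exp(-dt / tau_w)
    c.s = s_inf - (s_inf - c.s) * np.exp(-dt / tau_s)


def _step_tnnp(state: TissueState, p: TNNPParams, cfg: NumericsConfig,
               stimulus, diffusion_only):
    c = state.cell
    dt_s = cfg.dt
    dt_ms = dt_s * 1e3              # ionic rates are per millisecond
    lap = laplacian9(c.V, cfg.h)
    if diffusion_only:
        c.V = c.V + dt_s * p.D * lap
        return
    stim = stimulus if stimulus is not None else 0.0
    derivs, rates = tnnp_rhs(c, p, I_stim=stim, validate=False)
    c.V = c.V + dt_s * p.D * lap + dt_ms * derivs["V"]
    for g in TNNP_GATES:
        y_inf, tau_y = rates[g]
        setattr(c, g, y_inf - (y_inf - getattr(c, g)) * np.exp(-dt_ms / tau_y))
    for name in ("Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_SS", "R_bar"):
        setattr(c, name, getattr(c, name) + dt_ms * derivs[name])


def _excitation_threshold(state: TissueState, params) -> float:
    # BOCF: fast-inward activation threshold theta_v; TNNP: -70 mV
    return params.theta_v if state.model == "bocf" else -70.0


def run_episode(initial: TissueState, params, cfg: NumericsConfig,
                t_max: float,
                observers: Sequence[Callable[[TissueState], None]] = (),
                *, sample_interval: float = 0.01,
                confirm_window: float = 0.2,
                stimulus: Optional[Callable[[float], Optional[np.ndarray]]] = None,
                check_interval: float = 0.01) -> EpisodeRecord:
    """Advance until self-termination, t_max, or numerical blow-up.

    Observers are invoked every ``sample_interval`` seconds of simulated
    time (and once at t = 0).  Self-termination is declared when the
    maximum potential stays below the excitation threshold continuously
    for ``confirm_window`` seconds; the recorded lifetime is the time of
    the last downward threshold crossing, not the end of the window.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    cfg.check_stability(params.D)
    state = initial
    thr = _excitation_threshold(state, params)

    n_steps = int(round(t_max / cfg.dt))
    sample_every = max(1, int(round(sample_interval / cfg.dt)))
    check_every = max(1, int(round(check_interval / cfg.dt)))

    for obs in observers:
        obs(state)

    quiet_since = None  # time of last downward crossing, None while active
    if np.max(state.potential) < thr:
        quiet_since = state.t

    for i in range(n_steps):
        step(state, params, cfg,
             stimulus=stimulus(state.t) if stimulus is not None else None,
             check_stability=False)
        if (i + 1) % check_every == 0 or (i + 1) % sample_every == 0:
            vmax = np.max(state.potential)
            if not np.isfinite(vmax):
                return EpisodeRecord(lifetime=state.t, status=BLOWUP,
                                     area=state.grid.area)
            if vmax < thr:
                if quiet_since is None:
                    quiet_since = state.t
                elif state.t - quiet_since >= confirm_window:
                    for obs in observers:
                        obs(state)
                    return EpisodeRecord(lifetime=quiet_since, status=TERMINATED,
                                         area=state.grid.area)
            else:
                quiet_since = None
        if (i + 1) % sample_every == 0:
            for obs in observers:
                obs(state)

    if quiet_since is not None and state.t - quiet_since >= confirm_window:
        return EpisodeRecord(lifetime=quiet_since, status=TERMINATED,
                             area=state.grid.area)
    return EpisodeRecord(lifetime=t_max, status=CENSORED, area=state.grid.area)
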