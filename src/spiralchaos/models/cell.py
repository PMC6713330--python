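"""Single-cell (zero-dimensional) time stepping for both models.

Same scheme as the tissue integrator — explicit Euler for potential and
concentrations, Rush-Larsen exponential update for gates — but without a
grid, used for action-potential diagnostics and fixed-point tests.
Python-float arithmetic, deliberately simple.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .bocf import BOCFParams, BOCFState, bocf_currents, bocf_gating_rhs
from .tnnp import TNNP_GATES, TNNPParams, TNNPState, tnnp_rhs


def integrate_bocf_cell(state: BOCFState, p: BOCFParams, dt: float,
                        n_steps: int, stim: Callable[[float], float] | None = None,
                        record_every: int = 0):
    """Advance a single BOCF cell; dt in seconds.

    ``stim(t)`` returns J_stim in 1/s.  With ``record_every`` > 0, returns
    ``(state, t_rec, u_rec)``; otherwise just the final state.
    """
    st = state.copy()
    t = 0.0
    t_rec, u_rec = [], []
    for i in range(n_steps):
        J_fi, J_so, J_si = bocf_currents(st, p, validate=False)
        J_stim = stim(t) if stim is not None else 0.0
        _, (v_inf, tau_v, w_inf, tau_w, s_inf, tau_s) = bocf_gating_rhs(
            st, p, validate=False)
        st.u = st.u - dt * (J_fi + J_so + J_si + J_stim)
        st.v = v_inf - (v_inf - st.v) * np.exp(-dt / tau_v)
        st.w = w_inf - (w_inf - st.w) * np.exp(-dt / tau_w)
        st.s = s_inf - (s_inf - st.s) * np.exp(-dt / tau_s)
        t += dt
        if record_every and (i + 1) % record_every == 0:
            t_rec.append(t)
            u_rec.append(float(np.asarray(st.u)))
    if record_every:
        return st, np.array(t_rec), np.array(u_rec)
    return st


def integrate_tnnp_cell(state: TNNPState, p: TNNPParams, dt_ms: float,
                        n_steps: int, stim: Callable[[float], float] | None = None,
                        record_every: int = 0):
    """Advance a single TNNP cell; dt in MILLISECONDS (native model unit).

    ``stim(t_ms)`` returns I_stim in pA/pF.  With ``record_every`` > 0,
    returns ``(state, t_rec_ms, V_rec)``.
    """
    st = state.copy()
    t = 0.0
    t_rec, v_rec = [], []
    for i in range(n_steps):
        I_stim = stim(t) if stim is not None else 0.0
        derivs, rates = tnnp_rhs(st, p, I_stim=I_stim, validate=False)
        for g in TNNP_GATES:
            y_inf, tau_y = rates[g]
            y = getattr(st, g)
            setattr(st, g, y_inf - (y_inf - y) * np.exp(-dt_ms / tau_y))
        for name in ("V", "Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_SS", "R_bar"):
            setattr(st, name, getattr(st, name) + dt_ms * derivs[name])
        t += dt_ms
        if record_every and (i + 1) % record_every == 0:
            t_rec.append(t)
            v_rec.append(float(np.asarray(st.V)))
    if record_every:
        return st, np.array(t_rec), np.array(v_rec)
    return st
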