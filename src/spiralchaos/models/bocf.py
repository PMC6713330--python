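"""Bueno-Orovio–Cherry–Fenton (BOCF) minimal ventricular model.

The BOCF model describes the net transmembrane current of a human
ventricular cardiomyocyte with three effective contributions — a fast
inward current J_fi, a slow outward current J_so and a slow inward
current J_si — acting on a dimensionless membrane potential

    u = (V_m - V_rest) / (V_fi - V_rest),

together with three gating variables v, w, s in [0, 1].  All currents
here are rescaled by C_m (V_fi - V_rest) and therefore carry units of
inverse time (1/s; the package-internal time unit is seconds, parameter
files storing millisecond time constants are converted on load).

Everything in this module is zero-dimensional: pure reaction terms on
arrays of any shape, independent of the spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Tuple

import numpy as np
import yaml

__all__ = [
    "BOCFParams",
    "BOCFState",
    "load_bocf_params",
    "heaviside",
    "bocf_currents",
    "bocf_gating_rhs",
    "bocf_rhs",
    "rescale_potential",
    "unscale_potential",
]


def heaviside(x):
    """Step function with the right-continuous convention H(0) = 1."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


# names of the entries in the parameter file that are true time constants
# (stored in ms, converted to s on load).  tau_winf is a dimensionless
# slope parameter despite its name and must stay untouched.
_TIME_CONSTANTS = (
    "tau_v1minus", "tau_v2minus", "tau_vplus",
    "tau_w1minus", "tau_w2minus", "tau_wplus",
    "tau_fi", "tau_o1", "tau_o2", "tau_so1", "tau_so2",
    "tau_s1", "tau_s2", "tau_si",
)


@dataclass(frozen=True)
class BOCFParams:
    """Full BOCF parameter block (time constants in seconds).

    ``set_name`` records which published column the values came from
    ("TNNP" reproduces ten Tusscher-Noble-Noble-Panfilov dynamics and is
    the default for spiral-chaos studies; "EPI" is an optional
    passthrough).
    """

    u_o: float
    u_u: float
    theta_v: float
    theta_w: float
    theta_vminus: float
    theta_o: float
    tau_v1minus: float
    tau_v2minus: float
    tau_vplus: float
    tau_w1minus: float
    tau_w2minus: float
    k_wminus: float
    u_wminus: float
    tau_wplus: float
    tau_fi: float
    tau_o1: float
    tau_o2: float
    tau_so1: float
    tau_so2: float
    k_so: float
    u_so: float
    tau_s1: float
    tau_s2: float
    k_s: float
    u_s: float
    tau_si: float
    tau_winf: float
    w_infstar: float
    V_rest: float = -84.0          # mV
    V_fi: float = 1.7              # mV
    D: float = 200.0               # mm^2/s, isotropic
    Cm: float = 1.0                # enters only through the current rescaling
    set_name: str = "TNNP"

    def __post_init__(self):
        for f in fields(self):
            if f.name.startswith("tau_") and f.name != "tau_winf":
                if getattr(self, f.name) <= 0:
                    raise ValueError(f"{f.name} must be > 0")
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.V_fi <= self.V_rest:
            raise ValueError("V_fi must exceed V_rest")
        if not (self.u_o < self.theta_v < self.u_u):
            raise ValueError("require u_o < theta_v < u_u")


@dataclass
class BOCFState:
    """Dimensionless potential u and gates v, w, s (arrays of one shape)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    s: np.ndarray

    @classmethod
    def resting(cls, shape=(), p: "BOCFParams | None" = None):
        """Global resting state: u = 0, v = w = 1, s at its u = 0 steady state.

        With parameters supplied the state is an exact fixed point of the
        reaction terms; without them s falls back to 0 (it relaxes to
        s_inf(0) within a few tau_s1 anyway).
        """
        s0 = 0.0 if p is None else (1.0 + np.tanh(p.k_s * (0.0 - p.u_s))) / 2.0
        return cls(
            u=np.zeros(shape),
            v=np.ones(shape),
            w=np.ones(shape),
            s=np.full(shape, s0),
        )

    def validate(self):
        for name in ("u", "v", "w", "s"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in BOCF state field '{name}'")
        for name in ("v", "w", "s"):
            a = getattr(self, name)
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError(f"gating variable '{name}' outside [0, 1]")

    def copy(self):
        return BOCFState(self.u.copy(), self.v.copy(), self.w.copy(), self.s.copy())


def load_bocf_params(set_name: str | None = None) -> BOCFParams:
    """Load a parameter set from the versioned file shipped with the package.

    Millisecond time constants are converted to seconds here; nothing else
    is touched.
    """
    ref = resources.files("spiralchaos.models").joinpath("data/bocf_params.yaml")
    doc = yaml.safe_load(ref.read_text())
    if set_name is None:
        set_name = doc["default_set"]
    raw = dict(doc["sets"][set_name])
    assert doc["time_unit"] == "ms"
    for k in _TIME_CONSTANTS:
        raw[k] = raw[k] * 1e-3
    return BOCFParams(
        **raw,
        V_rest=doc["rescaling"]["V_rest_mV"],
        V_fi=doc["rescaling"]["V_fi_mV"],
        D=doc["diffusion"]["D_mm2_per_s"],
        set_name=set_name,
    )


def bocf_currents(state: BOCFState, p: BOCFParams, *, validate: bool = True
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescaled currents (J_fi, J_so, J_si), each in 1/s.

    J_fi = -v H(u - theta_v)(u - theta_v)(u_u - u)/tau_fi
    J_so = (u - u_o)(1 - H(u - theta_w))/tau_o(u) + H(u - theta_w)/tau_so(u)
    J_si = -H(u - theta_w) w s / tau_si

    with the u-dependent time constants

    tau_o(u)  = tau_o1  for u < theta_o else tau_o2
    tau_so(u) = tau_so1 + (tau_so2 - tau_so1)(1 + tanh(k_so (u - u_so)))/2
    """
    if validate:
        state.validate()
    u, v, w, s = state.u, state.v, state.w, state.s
    Hv = heaviside(u - p.theta_v)
    Hw = heaviside(u - p.theta_w)
    Ho = heaviside(u - p.theta_o)

    tau_o = (1.0 - Ho) * p.tau_o1 + Ho * p.tau_o2
    tau_so = p.tau_so1 + (p.tau_so2 - p.tau_so1) * (
        1.0 + np.tanh(p.k_so * (u - p.u_so))
    ) / 2.0

    J_fi = -v * Hv * (u - p.theta_v) * (p.u_u - u) / p.tau_fi
    J_so = (u - p.u_o) * (1.0 - Hw) / tau_o + Hw / tau_so
    J_si = -Hw * w * s / p.tau_si
    return J_fi, J_so, J_si


def bocf_gating_rhs(state: BOCFState, p: BOCFParams, *, validate: bool = True):
    """Gate dynamics in both raw-derivative and Rush-Larsen form.

    Returns ``(dv, dw, ds), (v_inf, tau_v, w_inf, tau_w, s_inf, tau_s)``
    where each gate obeys dy/dt = (y_inf(u) - y)/tau_y(u) exactly (the two
    forms are algebraically identical; the (y_inf, tau_y) pair is what the
    Rush-Larsen exponential update consumes).
    """
    if validate:
        state.validate()
    u, v, w, s = state.u, state.v, state.w, state.s
    Hv = heaviside(u - p.theta_v)
    Hw = heaviside(u - p.theta_w)
    Hvm = heaviside(u - p.theta_vminus)
    Ho = heaviside(u - p.theta_o)

    # v gate: relaxes to v_inf below theta_v with tau_v-, decays above with tau_v+
    tau_vminus = (1.0 - Hvm) * p.tau_v1minus + Hvm * p.tau_v2minus
    v_inf_sub = 1.0 - Hvm                       # 1 for u < theta_v-, else 0
    v_inf = (1.0 - Hv) * v_inf_sub              # 0 above theta_v
    tau_v = (1.0 - Hv) * tau_vminus + Hv * p.tau_vplus

    # w gate
    tau_wminus = p.tau_w1minus + (p.tau_w2minus - p.tau_w1minus) * (
        1.0 + np.tanh(p.k_wminus * (u - p.u_wminus))
    ) / 2.0
    w_inf_sub = (1.0 - Ho) * (1.0 - u / p.tau_winf) + Ho * p.w_infstar
    w_inf = (1.0 - Hw) * w_inf_sub
    tau_w = (1.0 - Hw) * tau_wminus + Hw * p.tau_wplus

    # s gate
    s_inf = (1.0 + np.tanh(p.k_s * (u - p.u_s))) / 2.0
    tau_s = (1.0 - Hw) * p.tau_s1 + Hw * p.tau_s2

    if np.any(tau_v == 0) or np.any(tau_w == 0) or np.any(tau_s == 0):
        raise ValueError("gate time constant vanished")

    dv = (v_inf - v) / tau_v
    dw = (w_inf - w) / tau_w
    ds = (s_inf - s) / tau_s
    return (dv, dw, ds), (v_inf, tau_v, w_inf, tau_w, s_inf, tau_s)


def bocf_rhs(state: BOCFState, p: BOCFParams, J_stim=0.0, *, validate: bool = True):
    """Full zero-dimensional reaction terms.

    Returns ``(du, dv, dw, ds)`` with
    du/dt = -(J_fi + J_so + J_si + J_stim) (no diffusion here).
    """
    J_fi, J_so, J_si = bocf_currents(state, p, validate=validate)
    (dv, dw, ds), _ = bocf_gating_rhs(state, p, validate=False)
    du = -(J_fi + J_so + J_si + J_stim)
    return du, dv, dw, ds


def rescale_potential(V_m, p: BOCFParams):
    """Affine map V_m [mV] -> dimensionless u."""
    if p.V_fi == p.V_rest:
        raise ValueError("V_fi must differ from V_rest")
    return (np.asarray(V_m) - p.V_rest) / (p.V_fi - p.V_rest)


def unscale_potential(u, p: BOCFParams):
    """Inverse of :func:`rescale_potential`: u -> V_m [mV]."""
    if p.V_fi == p.V_rest:
        raise ValueError("V_fi must differ from V_rest")
    return p.V_rest + np.asarray(u) * (p.V_fi - p.V_rest)
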