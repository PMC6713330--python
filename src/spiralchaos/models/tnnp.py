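"""ten Tusscher-Noble-Noble-Panfilov human ventricular model (2006 revision).

Twelve transmembrane currents (I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1,
I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa), twelve gating variables and
six further state variables for the intracellular ion dynamics
(Na_i, K_i, Ca_i, Ca_SR, Ca_SS and the ryanodine-receptor adaptation
variable R_bar).  Epicardial parameter set; the "slope18" variant applies
the published restitution-steepening changes that enable spiral breakup.

Conventions: V in mV, time in ms INSIDE this module (the native unit of
the published rate formulas), concentrations in mM, currents in pA/pF.
dV/dt = -(I_ion + I_stim) with per-capacitance currents, so the membrane
capacitance does not appear explicitly in the voltage equation; the
tissue capacitance override is metadata used to convert physical
stimulus current densities.  The spatial integrator converts between the
package-internal second-based clock and this module's millisecond rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, Tuple

import numpy as np
import yaml

__all__ = [
    "TNNPParams",
    "TNNPState",
    "load_tnnp_params",
    "tnnp_currents",
    "tnnp_gate_rates",
    "tnnp_rhs",
    "TNNP_GATES",
]

TNNP_GATES = ("m", "h", "j", "d", "f", "f2", "fCass", "r", "s", "xr1", "xr2", "xs")
_CONCENTRATIONS = ("Na_i", "K_i", "Ca_i", "Ca_SR", "Ca_SS")


@dataclass(frozen=True)
class TNNPParams:
    """Constant block of the revised TNNP model (epicardial).

    ``tau_f_mult_depol`` multiplies the f-gate time constant at V > 0 mV;
    the value 2.0 is part of the slope-1.8 breakup variant.
    """

    R: float
    T: float
    F: float
    Cm: float
    V_c: float
    V_sr: float
    V_ss: float
    K_o: float
    Na_o: float
    Ca_o: float
    G_Na: float
    G_K1: float
    G_to: float
    G_Kr: float
    G_Ks: float
    G_CaL: float
    G_bNa: float
    G_bCa: float
    G_pK: float
    G_pCa: float
    K_pCa: float
    P_NaK: float
    K_mK: float
    K_mNa: float
    k_NaCa: float
    gamma: float
    K_mCa: float
    K_mNai: float
    k_sat: float
    alpha: float
    p_KNa: float
    V_rel: float
    k1_prime: float
    k2_prime: float
    k3: float
    k4: float
    EC: float
    max_sr: float
    min_sr: float
    V_leak: float
    V_xfer: float
    Vmax_up: float
    K_up: float
    Buf_c: float
    K_buf_c: float
    Buf_sr: float
    K_buf_sr: float
    Buf_ss: float
    K_buf_ss: float
    tau_f_mult_depol: float = 1.0
    Cm_tissue: float = 0.002      # uF/mm^2, tissue-level override
    D: float = 154.0              # mm^2/s, isotropic
    variant: str = "baseline"

    def __post_init__(self):
        if self.Cm <= 0 or self.Cm_tissue <= 0:
            raise ValueError("capacitance must be > 0")
        if self.D <= 0:
            raise ValueError("D must be > 0")

    @property
    def RTONF(self) -> float:
        return self.R * self.T / self.F


@dataclass
class TNNPState:
    """All 19 state variables as arrays of one common shape."""

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    j: np.ndarray
    d: np.ndarray
    f: np.ndarray
    f2: np.ndarray
    fCass: np.ndarray
    r: np.ndarray
    s: np.ndarray
    xr1: np.ndarray
    xr2: np.ndarray
    xs: np.ndarray
    Na_i: np.ndarray
    K_i: np.ndarray
    Ca_i: np.ndarray
    Ca_SR: np.ndarray
    Ca_SS: np.ndarray
    R_bar: np.ndarray

    VAR_NAMES = ("V",) + TNNP_GATES + _CONCENTRATIONS + ("R_bar",)

    @classmethod
    def resting(cls, shape=()):
        """Published epicardial resting values broadcast to ``shape``."""
        rest = _load_doc()["resting_state"]
        return cls(**{k if k != "V" else "V": np.full(shape, float(rest[k]))
                      for k in cls.VAR_NAMES})

    def validate(self):
        for name in self.VAR_NAMES:
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in TNNP state field '{name}'")
        for name in TNNP_GATES:
            a = getattr(self, name)
            if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
                raise ValueError(f"gating variable '{name}' outside [0, 1]")
        for name in _CONCENTRATIONS:
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"concentration '{name}' must be positive")

    def copy(self):
        return TNNPState(**{k: getattr(self, k).copy() for k in self.VAR_NAMES})


def _load_doc():
    ref = resources.files("spiralchaos.models").joinpath("data/tnnp_params.yaml")
    return yaml.safe_load(ref.read_text())


def load_tnnp_params(variant: str | None = None) -> TNNPParams:
    """Load the epicardial constants, optionally with the breakup variant."""
    doc = _load_doc()
    if variant is None:
        variant = doc["default_variant"]
    raw = {k: float(v) for k, v in doc["constants"].items()}
    for k, v in doc["variants"][variant].items():
        raw[k] = float(v)
    return TNNPParams(
        **raw,
        Cm_tissue=float(doc["tissue"]["Cm_tissue_uF_per_mm2"]),
        D=float(doc["tissue"]["D_mm2_per_s"]),
        variant=variant,
    )


def tnnp_currents(state: TNNPState, p: TNNPParams, *, validate: bool = True
                  ) -> Dict[str, np.ndarray]:
    """All twelve transmembrane currents plus SR fluxes, keyed by name.

    Currents in pA/pF; SR fluxes (I_up, I_leak, I_rel, I_xfer) in mM/ms.
    """
    if validate:
        state.validate()
    V = state.V
    rtonf = p.RTONF
    vfrt = V / rtonf

    E_Na = rtonf * np.log(p.Na_o / state.Na_i)
    E_K = rtonf * np.log(p.K_o / state.K_i)
    E_Ks = rtonf * np.log((p.K_o + p.p_KNa * p.Na_o)
                          / (state.K_i + p.p_KNa * state.Na_i))
    E_Ca = 0.5 * rtonf * np.log(p.Ca_o / state.Ca_i)

    I_Na = p.G_Na * state.m ** 3 * state.h * state.j * (V - E_Na)

    # L-type Ca current, GHK-type driving term about +15 mV
    expv = np.exp(2.0 * (V - 15.0) / rtonf)
    denom = np.where(np.abs(expv - 1.0) < 1e-12, 1e-12, expv - 1.0)
    I_CaL = (p.G_CaL * state.d * state.f * state.f2 * state.fCass
             * 4.0 * (V - 15.0) * (p.F / rtonf)
             * (0.25 * state.Ca_SS * expv - p.Ca_o) / denom)

    I_to = p.G_to * state.r * state.s * (V - E_K)
    I_Ks = p.G_Ks * state.xs ** 2 * (V - E_Ks)
    I_Kr = p.G_Kr * np.sqrt(p.K_o / 5.4) * state.xr1 * state.xr2 * (V - E_K)

    a_K1 = 0.1 / (1.0 + np.exp(0.06 * (V - E_K - 200.0)))
    b_K1 = ((3.0 * np.exp(0.0002 * (V - E_K + 100.0))
             + np.exp(0.1 * (V - E_K - 10.0)))
            / (1.0 + np.exp(-0.5 * (V - E_K))))
    xK1_inf = a_K1 / (a_K1 + b_K1)
    I_K1 = p.G_K1 * np.sqrt(p.K_o / 5.4) * xK1_inf * (V - E_K)

    I_NaCa = (p.k_NaCa
              * (np.exp(p.gamma * vfrt) * state.Na_i ** 3 * p.Ca_o
                 - np.exp((p.gamma - 1.0) * vfrt) * p.Na_o ** 3 * state.Ca_i
                 * p.alpha)
              / ((p.K_mNai ** 3 + p.Na_o ** 3) * (p.K_mCa + p.Ca_o)
                 * (1.0 + p.k_sat * np.exp((p.gamma - 1.0) * vfrt))))

    I_NaK = (p.P_NaK * p.K_o * state.Na_i
             / ((p.K_o + p.K_mK) * (state.Na_i + p.K_mNa)
                * (1.0 + 0.1245 * np.exp(-0.1 * vfrt)
                   + 0.0353 * np.exp(-vfrt))))

    I_pCa = p.G_pCa * state.Ca_i / (p.K_pCa + state.Ca_i)
    I_pK = p.G_pK * (V - E_K) / (1.0 + np.exp((25.0 - V) / 5.98))
    I_bNa = p.G_bNa * (V - E_Na)
    I_bCa = p.G_bCa * (V - E_Ca)

    # SR calcium handling
    kcasr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.EC / state.Ca_SR) ** 2)
    k1 = p.k1_prime / kcasr
    k2 = p.k2_prime * kcasr
    O = k1 * state.Ca_SS ** 2 * state.R_bar / (p.k3 + k1 * state.Ca_SS ** 2)
    I_rel = p.V_rel * O * (state.Ca_SR - state.Ca_SS)
    I_leak = p.V_leak * (state.Ca_SR - state.Ca_i)
    I_up = p.Vmax_up / (1.0 + (p.K_up / state.Ca_i) ** 2)
    I_xfer = p.V_xfer * (state.Ca_SS - state.Ca_i)

    return {
        "I_Na": I_Na, "I_CaL": I_CaL, "I_to": I_to, "I_Ks": I_Ks,
        "I_Kr": I_Kr, "I_K1": I_K1, "I_NaCa": I_NaCa, "I_NaK": I_NaK,
        "I_pCa": I_pCa, "I_pK": I_pK, "I_bCa": I_bCa, "I_bNa": I_bNa,
        "I_rel": I_rel, "I_leak": I_leak, "I_up": I_up, "I_xfer": I_xfer,
        "k2": k2,
    }


def tnnp_gate_rates(state: TNNPState, p: TNNPParams
                    ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """(y_inf, tau_y [ms]) for each of the twelve gates at the current V.

    fCass depends on the subspace calcium instead of V; it is included on
    the same footing so Rush-Larsen treats all gates uniformly.
    """
    V = state.V

    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b_m = (0.1 / (1.0 + np.exp((V + 35.0) / 5.0))
           + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0)))
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    lo = V < -40.0
    a_h = np.where(lo, 0.057 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(
        lo,
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    a_j = np.where(
        lo,
        ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
         * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    tau_j = 1.0 / (a_j + b_j)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = a_d * b_d + g_d

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    if p.tau_f_mult_depol != 1.0:
        tau_f = np.where(V > 0.0, tau_f * p.tau_f_mult_depol, tau_f)

    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))

    fCass_inf = 0.6 / (1.0 + (state.Ca_SS / 0.05) ** 2) + 0.4
    tau_fCass = 80.0 / (1.0 + (state.Ca_SS / 0.05) ** 2) + 2.0

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau_s = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
             + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1

    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    return {
        "m": (m_inf, tau_m), "h": (h_inf, tau_h), "j": (j_inf, tau_j),
        "d": (d_inf, tau_d), "f": (f_inf, tau_f), "f2": (f2_inf, tau_f2),
        "fCass": (fCass_inf, tau_fCass), "r": (r_inf, tau_r),
        "s": (s_inf, tau_s), "xr1": (xr1_inf, tau_xr1),
        "xr2": (xr2_inf, tau_xr2), "xs": (xs_inf, tau_xs),
    }


def tnnp_rhs(state: TNNPState, p: TNNPParams, I_stim=0.0, *,
             validate: bool = True, return_currents: bool = False):
    """Time derivatives of all 19 state variables (per ms).

    Returns ``(derivs, gate_rates)`` where ``derivs`` maps variable name
    -> dX/dt and ``gate_rates`` is the Rush-Larsen (y_inf, tau_y) table;
    with ``return_currents=True`` the current dict is appended.
    dV/dt = -(I_ion + I_stim) with I in pA/pF.
    """
    cur = tnnp_currents(state, p, validate=validate)
    rates = tnnp_gate_rates(state, p)

    I_ion = (cur["I_K1"] + cur["I_to"] + cur["I_Kr"] + cur["I_Ks"]
             + cur["I_CaL"] + cur["I_NaK"] + cur["I_Na"] + cur["I_bNa"]
             + cur["I_NaCa"] + cur["I_bCa"] + cur["I_pK"] + cur["I_pCa"])

    derivs = {"V": -(I_ion + I_stim)}
    for g in TNNP_GATES:
        y_inf, tau_y = rates[g]
        derivs[g] = (y_inf - getattr(state, g)) / tau_y

    conv = p.Cm / (p.V_c * p.F)  # pA/pF -> mM/ms in the cytosol

    buf_c = 1.0 / (1.0 + p.Buf_c * p.K_buf_c / (state.Ca_i + p.K_buf_c) ** 2)
    derivs["Ca_i"] = buf_c * (
        (cur["I_leak"] - cur["I_up"]) * p.V_sr / p.V_c + cur["I_xfer"]
        - (cur["I_bCa"] + cur["I_pCa"] - 2.0 * cur["I_NaCa"]) * conv / 2.0
    )

    buf_sr = 1.0 / (1.0 + p.Buf_sr * p.K_buf_sr / (state.Ca_SR + p.K_buf_sr) ** 2)
    derivs["Ca_SR"] = buf_sr * (cur["I_up"] - cur["I_rel"] - cur["I_leak"])

    buf_ss = 1.0 / (1.0 + p.Buf_ss * p.K_buf_ss / (state.Ca_SS + p.K_buf_ss) ** 2)
    derivs["Ca_SS"] = buf_ss * (
        -cur["I_CaL"] * p.Cm / (2.0 * p.V_ss * p.F)
        + cur["I_rel"] * p.V_sr / p.V_ss
        - cur["I_xfer"] * p.V_c / p.V_ss
    )

    derivs["Na_i"] = -(cur["I_Na"] + cur["I_bNa"]
                       + 3.0 * cur["I_NaK"] + 3.0 * cur["I_NaCa"]) * conv
    derivs["K_i"] = -(cur["I_K1"] + cur["I_to"] + cur["I_Kr"] + cur["I_Ks"]
                      - 2.0 * cur["I_NaK"] + cur["I_pK"] + I_stim) * conv

    derivs["R_bar"] = (-cur["k2"] * state.Ca_SS * state.R_bar
                       + p.k4 * (1.0 - state.R_bar))

    if return_currents:
        return derivs, rates, cur
    return derivs, rates
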