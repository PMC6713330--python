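"""Ground-truth generators for every analysis stage.

Each generator is a pure function of its parameters and a seed
(numpy PCG64 via ``np.random.default_rng``), and ships the planted
ground truth with the generated data so estimator tests compare against
the truth rather than hard-coded numbers:

* phase fields with planted singularities of known position and charge,
* exponentially distributed lifetime ensembles with known escape rate,
* integer spiral-count Markov chains with an absorbing zero state,
* noisy (A, <T>) samples following the type-II supertransient law
  <T> = exp[(a_tilde A)^gamma].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grid import Grid
from .phase import PhaseField
from .records import CENSORED, TERMINATED

__all__ = [
    "synthetic_phase_field", "synthetic_lifetimes", "synthetic_markov_series",
    "synthetic_scaling_samples", "markov_preset", "stationary_distribution",
    "MarkovChainSpec",
]


def synthetic_phase_field(singularities: Sequence[Tuple[float, float, int]],
                          grid: Grid, t: float = 0.0) -> PhaseField:
    """Phase field theta = wrap(sum_k q_k atan2(y - y_k, x - x_k)).

    Positions in mm; charges must be +-1.  A singularity lying exactly on
    a grid node is jittered by h/2 in both coordinates (the phase would
    be undefined there); the jitter keeps it inside the same cell.
    """
    ys, xs = np.meshgrid(np.arange(grid.n_y) * grid.h,
                         np.arange(grid.n_x) * grid.h, indexing="ij")
    theta = np.zeros(grid.shape)
    for (x0, y0, q) in singularities:
        if abs(q) != 1:
            raise ValueError("charges must be +-1")
        on_node = (abs(x0 / grid.h - round(x0 / grid.h)) < 1e-12
                   and abs(y0 / grid.h - round(y0 / grid.h)) < 1e-12)
        if on_node:
            x0, y0 = x0 + grid.h / 2, y0 + grid.h / 2
        theta = theta + q * np.arctan2(ys - y0, xs - x0)
    theta = np.angle(np.exp(1j * theta))
    theta = np.where(theta <= -np.pi, np.pi, theta)
    return PhaseField(theta=theta, h=grid.h, t=t)


def synthetic_lifetimes(kappa: float, n: int, seed: int,
                        censor_at: Optional[float] = None
                        ) -> List[Tuple[float, str]]:
    """n i.i.d. Exponential(kappa) lifetimes; values >= censor_at censored."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(1.0 / kappa, size=n)
    out = []
    for T in draws:
        if censor_at is not None and T >= censor_at:
            out.append((censor_at, CENSORED))
        else:
            out.append((float(T), TERMINATED))
    return out


@dataclass(frozen=True)
class MarkovChainSpec:
    """Spiral-count random walk: per-step jump probabilities by state.

    ``jumps[n]`` maps dN in {-2,-1,0,+1,+2} to its probability from
    state n; states above the largest key reuse the largest key's row
    (the chain is homogeneous in the bulk).  State 0 is absorbing.
    """

    jumps: Dict[int, Dict[int, float]]
    n_max: int = 60          # reflecting ceiling, keeps chains finite

    def row(self, n: int) -> Dict[int, float]:
        key = max(k for k in self.jumps if k <= n)
        return self.jumps[key]

    def validate(self):
        for n, row in self.jumps.items():
            tot = sum(row.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"row for state {n} sums to {tot}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("negative transition probability")
            if any(dn not in (-2, -1, 0, 1, 2) for dn in row):
                raise ValueError("jumps must be in {-2,-1,0,+1,+2}")


def markov_preset(kind: str) -> MarkovChainSpec:
    """Stylised spiral-count chains mimicking the two models' breakup modes.

    "bocf_like": the single-spiral state is sticky (exit probability
    0.02/step, mostly downward to termination) — wave breakup is rare, so
    N = 1 persists and episodes end through a long single-spiral tail.
    "tnnp_like": frequent breakup (exit probability 0.3/step from N = 1),
    so the count fluctuates until it hits zero "spontaneously".

    These presets encode the qualitative contrast only; they are test
    fixtures, not fits to any simulation.
    """
    bulk = {-2: 0.05, -1: 0.25, 0: 0.42, 1: 0.23, 2: 0.05}
    if kind == "bocf_like":
        return MarkovChainSpec(jumps={
            1: {-1: 0.012, 0: 0.98, 1: 0.006, 2: 0.002, -2: 0.0},
            2: bulk,
        })
    if kind == "tnnp_like":
        return MarkovChainSpec(jumps={
            1: {-1: 0.15, 0: 0.70, 1: 0.10, 2: 0.05, -2: 0.0},
            2: bulk,
        })
    raise ValueError(f"unknown preset {kind!r}")


def synthetic_markov_series(spec: MarkovChainSpec, n_episodes: int,
                            start_state: int, seed: int,
                            step_cap: int = 100_000,
                            dt_obs: float = 0.01
                            ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Run integer spiral-count chains to absorption at 0 or a step cap.

    Returns one (t, counts) pair per episode with uniform sampling
    interval ``dt_obs`` (seconds).  Ground truth is the ``spec`` itself.
    """
    spec.validate()
    if start_state < 1:
        raise ValueError("start_state must be >= 1")
    rng = np.random.default_rng(seed)
    episodes = []
    for _ in range(n_episodes):
        n = start_state
        counts = [n]
        for _ in range(step_cap):
            row = spec.row(n)
            dns = np.array(sorted(row))
            ps = np.array([row[d] for d in dns])
            n = int(np.clip(n + rng.choice(dns, p=ps), 0, spec.n_max))
            counts.append(n)
            if n == 0:
                break
        counts = np.asarray(counts, dtype=int)
        t = np.arange(len(counts)) * dt_obs
        episodes.append((t, counts))
    return episodes


def stationary_distribution(spec: MarkovChainSpec, n_max: Optional[int] = None
                            ) -> np.ndarray:
    """Stationary law of the chain conditioned on never terminating.

    Builds the transition matrix on {1..n_max} with the mass that would
    go to 0 redirected to stay (the quasi-stationary approximation used
    as the oracle for occupancy tests on long-lived chains).
    """
    if n_max is None:
        n_max = spec.n_max
    P = np.zeros((n_max, n_max))
    for i in range(1, n_max + 1):
        for dn, p in spec.row(i).items():
            jto = int(np.clip(i + dn, 1, n_max))
            P[i - 1, jto - 1] += p
    evals, evecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi


def synthetic_scaling_samples(a_tilde: float, gamma: float,
                              areas: Sequence[float], noise_sd: float,
                              seed: int) -> List[Tuple[float, float]]:
    """(A, <T>) pairs with <T> = exp[(a_tilde A)^gamma] * exp(eps).

    eps ~ Normal(0, noise_sd^2) is multiplicative log-normal noise.
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("areas must be > 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=len(areas)) if noise_sd > 0 else 0.0
    T = np.exp((a_tilde * areas) ** gamma) * np.exp(eps)
    return list(zip(areas.tolist(), np.atleast_1d(T).tolist()))
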