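"""Spiral-count statistics: the Markov-chain view of multi-spiral chaos.

Every analysis here consumes uniformly sampled N_spiral(t) series.  The
count of spiral waves performs a random walk on the nonnegative integers
with absorbing zero (self-termination); at sufficiently fine sampling
the walk moves by at most +-2 per step (pair creation/annihilation), so
the dynamics is summarised by five probabilities P_dN, dN in
{-2,-1,0,+1,+2}, per starting state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "TransitionStats", "SpiralMarkovEstimator",
    "time_average_spiral_number", "occupancy_distribution",
    "transition_probabilities", "termination_aligned_average",
    "single_spiral_dwell_statistics",
]

Series = Tuple[np.ndarray, np.ndarray]          # (t seconds, integer counts)
ALLOWED_JUMPS = (-2, -1, 0, 1, 2)


def _as_series_list(series_set) -> List[Series]:
    out = []
    for item in series_set:
        t, c = item
        t = np.asarray(t, dtype=float)
        c = np.asarray(c)
        if np.any(c < 0):
            raise ValueError("spiral counts must be nonnegative")
        out.append((t, c.astype(int)))
    return out


@dataclass
class TransitionStats:
    """Empirical jump probabilities P_dN per starting state N.

    ``probs[n]`` maps dN -> conditional frequency; ``counts[n]`` the raw
    transition counts.  Jumps outside {-2..+2} are never folded into the
    table — they are tallied in ``oversize_jumps`` as a diagnostic that
    the sampling interval is too coarse for the +-2 bound to hold.
    """

    probs: Dict[int, Dict[int, float]]
    counts: Dict[int, Dict[int, int]]
    oversize_jumps: int
    total_transitions: int
    dt_obs: float

    def pooled(self) -> Dict[int, float]:
        """P_dN pooled over all starting states."""
        tot: Dict[int, int] = {d: 0 for d in ALLOWED_JUMPS}
        for row in self.counts.values():
            for d, k in row.items():
                tot[d] += k
        s = sum(tot.values())
        return {d: (k / s if s else 0.0) for d, k in tot.items()}


def time_average_spiral_number(series_set, T_obs: float = 80.0, *,
                               settle_exclude: float = 1.0,
                               pre_termination_exclude: float = 0.0
                               ) -> Tuple[float, float]:
    """Time-averaged spiral count <N_spiral>_t and its standard deviation.

    Concatenates the usable portions of the given episodes — excluding
    ``settle_exclude`` seconds after episode start and
    ``pre_termination_exclude`` seconds before each termination — until
    at least ``T_obs`` seconds of samples are available, then averages.
    """
    series = _as_series_list(series_set)
    chunks = []
    total = 0.0
    for t, c in series:
        if len(t) < 2:
            continue
        dt = t[1] - t[0]
        t_end = t[-1] - pre_termination_exclude
        m = (t >= t[0] + settle_exclude) & (t <= t_end)
        if m.sum() == 0:
            continue
        chunks.append(c[m])
        total += m.sum() * dt
        if total >= T_obs:
            break
    if total < T_obs:
        raise ValueError(
            f"insufficient usable simulation time: {total:.2f} s available, "
            f"T_obs = {T_obs:.2f} s required")
    allc = np.concatenate(chunks)
    return float(allc.mean()), float(allc.std())


def occupancy_distribution(series_set) -> Dict[int, float]:
    """Relative frequency of each observed N_spiral value (sums to 1)."""
    series = _as_series_list(series_set)
    if not series:
        raise ValueError("empty series set")
    allc = np.concatenate([c for _, c in series])
    vals, counts = np.unique(allc, return_counts=True)
    total = counts.sum()
    return {int(v): float(k) / total for v, k in zip(vals, counts)}


class SpiralMarkovEstimator(BaseEstimator):
    """Empirical Markov transition statistics of spiral-count series.

    Parameters
    ----------
    lag : int, default 1
        Transition lag in samples.
    per_state : bool, default True
        Estimate P_dN separately for each starting state N (pooled
        estimates remain available via ``transition_stats_.pooled()``).

    Attributes
    ----------
    transition_stats_ : TransitionStats
    occupancy_ : dict
        Relative frequency of each count value.
    n_series_ : int
    """

    def __init__(self, lag: int = 1, per_state: bool = True):
        self.lag = lag
        self.per_state = per_state

    def fit(self, series_set, y=None) -> "SpiralMarkovEstimator":
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        series = _as_series_list(series_set)
        counts: Dict[int, Dict[int, int]] = {}
        oversize = 0
        total = 0
        dt_obs = np.nan
        for t, c in series:
            if len(t) >= 2:
                dt_obs = (t[1] - t[0]) * self.lag
            frm, to = c[:-self.lag], c[self.lag:]
            for a, b in zip(frm, to):
                if a == 0:
                    continue                      # absorbing state: no exits
                d = int(b) - int(a)
                total += 1
                if d in ALLOWED_JUMPS:
                    row = counts.setdefault(int(a), {j: 0 for j in ALLOWED_JUMPS})
                    row[d] += 1
                else:
                    oversize += 1
        probs: Dict[int, Dict[int, float]] = {}
        for n, row in sorted(counts.items()):
            s = sum(row.values())
            probs[n] = {d: k / s for d, k in row.items()}
        self.transition_stats_ = TransitionStats(
            probs=probs, counts=counts, oversize_jumps=oversize,
            total_transitions=total, dt_obs=float(dt_obs))
        self.occupancy_ = occupancy_distribution(series)
        self.n_series_ = len(series)
        return self


def transition_probabilities(series_set, lag: int = 1) -> TransitionStats:
    """Functional wrapper over :class:`SpiralMarkovEstimator`."""
    return SpiralMarkovEstimator(lag=lag).fit(series_set).transition_stats_


def termination_aligned_average(series_set
                                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                                           np.ndarray]:
    """Ensemble average of N_spiral aligned so termination occurs at t = 0.

    All series must end in the absorbed state (count 0).  Returns
    ``(t_aligned, mean, sd, n_contributing)`` where t_aligned <= 0 and
    each time offset averages only the episodes long enough to reach it.
    """
    series = _as_series_list(series_set)
    if not series:
        raise ValueError("empty series set")
    for _, c in series:
        if c[-1] != 0:
            raise ValueError("all series must be terminated (end at count 0)")
    dt = series[0][0][1] - series[0][0][0] if len(series[0][0]) > 1 else 1.0
    max_len = max(len(c) for _, c in series)
    t_aligned = -dt * np.arange(max_len)[::-1]
    sums = np.zeros(max_len)
    sqs = np.zeros(max_len)
    cnt = np.zeros(max_len, dtype=int)
    for _, c in series:
        k = len(c)
        sl = slice(max_len - k, max_len)
        sums[sl] += c
        sqs[sl] += c.astype(float) ** 2
        cnt[sl] += 1
    with np.errstate(invalid="ignore"):
        mean = sums / cnt
        var = sqs / cnt - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    return t_aligned, mean, sd, cnt


def single_spiral_dwell_statistics(series_set) -> Dict[str, List[int]]:
    """Durations of maximal runs at N = 1, split by how each run ends.

    Returns lists of run lengths (in samples) under keys
    "ending_in_termination" (next state 0), "ending_in_breakup" (next
    state >= 2) and "censored" (series ends while still at N = 1).
    """
    series = _as_series_list(series_set)
    if not series:
        raise ValueError("empty series set")
    out = {"ending_in_termination": [], "ending_in_breakup": [], "censored": []}
    for _, c in series:
        run = 0
        for i, v in enumerate(c):
            if v == 1:
                run += 1
            else:
                if run > 0:
                    key = ("ending_in_termination" if v == 0
                           else "ending_in_breakup")
                    out[key].append(run)
                run = 0
        if run > 0:
            out["censored"].append(run)
    return out
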