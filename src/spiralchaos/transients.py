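"""Transient-lifetime statistics: escape rate and supertransient scaling.

In a system with transient chaos the number of episodes still chaotic at
time t decays exponentially,

    N_Ch(t) ~ exp(-kappa t),                                   (escape law)

and the escape rate kappa approximates the inverse average lifetime,
kappa^-1 ~ <T>.  For type-II supertransients the average lifetime grows
exponentially with the domain area A,

    <T> ~ exp[(a_tilde A)^gamma].                              (size scaling)

Both fits are exposed as scikit-learn style estimators
(:class:`EscapeRateEstimator`, :class:`SupertransientScalingFit`) with
thin functional wrappers matching the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .integrator import TissueState
from .records import TERMINATED, EpisodeRecord

__all__ = [
    "detect_termination", "SurvivalCurve", "survival_curve",
    "EscapeRateEstimator", "fit_escape_rate",
    "SupertransientScalingFit", "fit_supertransient_scaling",
]


def detect_termination(state: TissueState, params, *,
                       quiet_time: float = 0.0,
                       confirm_window: float = 0.2) -> bool:
    """True iff the tissue has settled into the global resting state.

    The criterion is sub-threshold maximum potential (u < theta_v for
    BOCF, V_m < -70 mV for TNNP) sustained for ``confirm_window``
    seconds; ``quiet_time`` is how long the state has already been
    continuously sub-threshold.  A single snapshot (quiet_time = 0) is
    therefore never sufficient unless the window is zero.
    """
    thr = params.theta_v if state.model == "bocf" else -70.0
    if np.max(state.potential) >= thr:
        return False
    return quiet_time >= confirm_window


@dataclass
class SurvivalCurve:
    """N_Ch(t): number of episodes with lifetime >= t, on a time grid."""

    t: np.ndarray
    n_ch: np.ndarray
    n: int                      # ensemble size

    def __post_init__(self):
        if self.n_ch[0] != self.n:
            raise ValueError("N_Ch(0) must equal the ensemble size")
        if np.any(np.diff(self.n_ch) > 0):
            raise ValueError("survival curve must be nonincreasing")


def survival_curve(lifetimes: Sequence[Tuple[float, str]],
                   t_grid: Optional[np.ndarray] = None) -> SurvivalCurve:
    """Count N_Ch(t) = #{episodes with T >= t}.

    ``lifetimes`` holds (T, status) pairs; censored episodes are known to
    survive at least to their censoring time and count as such.  If no
    grid is given, the curve is evaluated at t = 0 and at every recorded
    lifetime (the exact empirical survival function).
    """
    if len(lifetimes) == 0:
        raise ValueError("empty ensemble")
    T = np.array([lt for lt, _ in lifetimes], dtype=float)
    if t_grid is None:
        t_grid = np.unique(np.concatenate([[0.0], T]))
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
    n_ch = (T[None, :] >= t_grid[:, None]).sum(axis=1)
    return SurvivalCurve(t=t_grid, n_ch=n_ch, n=len(lifetimes))


class EscapeRateEstimator(BaseEstimator):
    """Escape rate from an ensemble of transient lifetimes.

    Fits N0 * exp(-kappa t) to the empirical survival curve by nonlinear
    least squares, using only the points with N_Ch(t) > fit_threshold
    (a fraction of the ensemble size, default 10%) so the poorly-sampled
    exponential tail does not dominate.

    The survival-curve points share episodes and are therefore strongly
    correlated, so the naive least-squares covariance understates the
    parameter uncertainty badly.  ``kappa_sd_`` is instead computed by a
    seeded nonparametric bootstrap over episodes, which is honest about
    the ensemble size actually available.

    Parameters
    ----------
    fit_threshold_fraction : float, default 0.10
        Points with N_Ch(t) <= fraction * N are discarded before fitting.
    n_bootstrap : int, default 100
        Episode resamples used for the kappa standard error (0 disables
        the bootstrap; kappa_sd_ then falls back to the parametric
        exponential value kappa / sqrt(N)).
    bootstrap_seed : int, default 0
        Seed of the bootstrap resampler.

    Attributes
    ----------
    kappa_ : float
        Escape rate (1/s).
    avg_lifetime_ : float
        <T> = 1/kappa (s).
    kappa_sd_ : float
        Bootstrap standard deviation of kappa.
    n0_ : float
        Fitted amplitude of the exponential.
    covariance_ : ndarray, shape (2, 2)
        Raw least-squares covariance of (N0, kappa) — kept for
        diagnostics only; see kappa_sd_ for the usable uncertainty.
    fit_threshold_ : float
        The count threshold actually applied.
    n_points_ : int
        Number of survival-curve points retained.
    """

    def __init__(self, fit_threshold_fraction: float = 0.10,
                 n_bootstrap: int = 100, bootstrap_seed: int = 0):
        self.fit_threshold_fraction = fit_threshold_fraction
        self.n_bootstrap = n_bootstrap
        self.bootstrap_seed = bootstrap_seed

    def fit(self, lifetimes: Sequence[Tuple[float, str]],
            y=None) -> "EscapeRateEstimator":
        if isinstance(lifetimes, SurvivalCurve):
            curve = lifetimes
            pairs = None
            min_censor = np.inf
        else:
            pairs = list(lifetimes)
            curve = survival_curve(pairs)
            censor_times = [lt for lt, st in pairs if st != TERMINATED]
            min_censor = min(censor_times) if censor_times else np.inf
        n0, kappa, pcov, n_pts = self._fit_curve(curve, min_censor)
        self.n0_ = float(n0)
        self.kappa_ = float(kappa)
        self.avg_lifetime_ = 1.0 / float(kappa)
        self.covariance_ = pcov
        self.fit_threshold_ = float(self.fit_threshold_fraction * curve.n)
        self.n_points_ = int(n_pts)
        if self.n_bootstrap > 0 and pairs is not None:
            rng = np.random.default_rng(self.bootstrap_seed)
            boots = []
            for _ in range(self.n_bootstrap):
                idx = rng.integers(0, len(pairs), size=len(pairs))
                bpairs = [pairs[i] for i in idx]
                bcens = [lt for lt, st in bpairs if st != TERMINATED]
                bmin = min(bcens) if bcens else np.inf
                try:
                    _, bk, _, _ = self._fit_curve(survival_curve(bpairs), bmin)
                    boots.append(bk)
                except (ValueError, RuntimeError):
                    continue
            if len(boots) >= max(10, self.n_bootstrap // 2):
                self.kappa_sd_ = float(np.std(boots, ddof=1))
            else:
                self.kappa_sd_ = self.kappa_ / np.sqrt(curve.n)
        else:
            self.kappa_sd_ = self.kappa_ / np.sqrt(curve.n)
        return self

    def _fit_curve(self, curve: SurvivalCurve, min_censor: float):
        thr = self.fit_threshold_fraction * curve.n
        # beyond the earliest censoring time the empirical curve is biased
        # (censored episodes stop contributing); exclude that region
        keep = (curve.n_ch > thr) & (curve.t < min_censor)
        t, n_ch = curve.t[keep], curve.n_ch[keep].astype(float)
        if len(t) < 3:
            raise ValueError("need at least 3 survival-curve points above "
                             "the fit threshold")
        # initial guess: log-linear slope over the retained points
        slope = np.polyfit(t, np.log(n_ch), 1)[0]
        k0 = max(-slope, 1e-12)
        popt, pcov = curve_fit(
            lambda tt, n0, k: n0 * np.exp(-k * tt),
            t, n_ch, p0=(float(curve.n), k0), maxfev=10_000)
        n0, kappa = popt
        if kappa <= 0:
            raise RuntimeError(
                f"escape-rate fit did not converge to kappa > 0 "
                f"(guess {k0:g}, n = {curve.n})")
        return n0, kappa, pcov, len(t)

    def predict(self, t) -> np.ndarray:
        """Expected N_Ch(t) under the fitted escape law."""
        if not hasattr(self, "kappa_"):
            raise RuntimeError("estimator is not fitted")
        return self.n0_ * np.exp(-self.kappa_ * np.asarray(t))

    def __sklearn_is_fitted__(self):
        return hasattr(self, "kappa_")


def fit_escape_rate(lifetimes, fit_threshold_fraction: float = 0.10
                    ) -> EscapeRateEstimator:
    """Functional wrapper: fit and return the estimator."""
    return EscapeRateEstimator(fit_threshold_fraction).fit(lifetimes)


class SupertransientScalingFit(BaseEstimator):
    """Type-II supertransient scaling fit <T> = exp[(a_tilde A)^gamma].

    Linear least squares of ln ln<T> on ln A: the slope is gamma and the
    intercept gamma * ln(a_tilde).  Lifetimes enter in seconds, so the
    domain of validity is <T> > 1 s (ln<T> > 0); areas in mm^2.

    Attributes
    ----------
    a_tilde_ : float
        Inverse-area scale (1/mm^2).
    gamma_ : float
        Scaling exponent (dimensionless).
    a_tilde_sd_, gamma_sd_ : float
        Standard deviations propagated from the regression covariance
        (delta method for a_tilde).
    areas_ : ndarray
        Domain areas used in the fit.
    """

    def fit(self, areas: Sequence[float], avg_lifetimes: Sequence[float]
            ) -> "SupertransientScalingFit":
        A = np.asarray(areas, dtype=float)
        T = np.asarray(avg_lifetimes, dtype=float)
        if len(A) != len(T):
            raise ValueError("areas and lifetimes must have equal length")
        if len(A) < 3:
            raise ValueError("need at least 3 domain sizes")
        if np.any(A <= 0):
            raise ValueError("areas must be > 0")
        if np.any(T <= 1.0):
            raise ValueError(
                "all average lifetimes must exceed 1 s: ln<T> must be "
                "positive for the double-logarithmic fit")
        x = np.log(A)
        y = np.log(np.log(T))
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        gamma = slope
        a_tilde = np.exp(intercept / gamma)
        # delta method: a_tilde = exp(c/g) with (g, c) the fitted pair
        dg = -a_tilde * intercept / gamma ** 2
        dc = a_tilde / gamma
        var_a = (dg * dg * cov[0, 0] + dc * dc * cov[1, 1]
                 + 2.0 * dg * dc * cov[0, 1])
        self.gamma_ = float(gamma)
        self.a_tilde_ = float(a_tilde)
        self.gamma_sd_ = float(np.sqrt(cov[0, 0]))
        self.a_tilde_sd_ = float(np.sqrt(max(var_a, 0.0)))
        self.covariance_ = cov
        self.areas_ = A
        return self

    def predict(self, areas) -> np.ndarray:
        """Expected <T> (s) at the given areas under the fitted law."""
        if not hasattr(self, "gamma_"):
            raise RuntimeError("estimator is not fitted")
        A = np.asarray(areas, dtype=float)
        return np.exp((self.a_tilde_ * A) ** self.gamma_)


def fit_supertransient_scaling(areas, avg_lifetimes) -> SupertransientScalingFit:
    """Functional wrapper: fit and return the estimator."""
    return SupertransientScalingFit().fit(areas, avg_lifetimes)
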