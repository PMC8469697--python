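"""Rise-and-fall kinetic modelling of plate-reader time courses.

A transient receptor-proximity or second-messenger signal that rises and
then decays is described by the difference of two exponentials,

    E(t) = C / (K1 - K2) * (exp(-K2 t) - exp(-K1 t)),        K1 > K2 >= 0,

where K1 is the fast (rise) rate and K2 the slow (decay) rate.  The
characteristic half-time reported per ligand and readout is

    T1/2 = ln(2) / K1,

the half-time of the fast exponential (natural logarithm; a base-10 log
would be dimensionally wrong for an exp(-K1 t) process).  Sustained,
non-decaying signals are the K2 = 0 boundary of the same family, and the
K1 == K2 limit is the continuous limit C * t * exp(-K1 t).

The module also integrates traces to the area under the curve (AUC) at a
chosen endpoint, the summary used to build concentration/activity curves.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares

from .types import KineticFit, KineticParams, KineticTrace

__all__ = ["eval_rise_fall", "rise_fall_auc", "fit_rise_fall", "trace_auc", "amplitude_to_c"]

# below this relative rate separation the two-exponential form loses
# precision and the analytic K1==K2 limit takes over
_EQUAL_RATE_RTOL = 1e-9


def eval_rise_fall(kp: KineticParams | tuple[float, float, float], t) -> np.ndarray | float:
    """Evaluate the rise-and-fall curve at times ``t`` (minutes, >= 0).

    Accepts a :class:`KineticParams` or a raw ``(C, K1, K2)`` tuple; the
    tuple form does not enforce K1 > K2 so the swap symmetry
    ``(C, K1, K2) == (-C, K2, K1)`` can be exercised directly.
    """
    if isinstance(kp, KineticParams):
        c, k1, k2 = kp.c, kp.k1, kp.k2
    else:
        c, k1, k2 = kp
    if not all(math.isfinite(v) for v in (c, k1, k2)):
        raise ValueError("NaN or infinite kinetic parameters")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative time")
    denom = k1 - k2
    if abs(denom) <= _EQUAL_RATE_RTOL * max(abs(k1), abs(k2), 1.0):
        out = c * t_arr * np.exp(-k1 * t_arr)
    else:
        out = c / denom * (np.exp(-k2 * t_arr) - np.exp(-k1 * t_arr))
    return out if isinstance(t, np.ndarray) else float(out) if np.isscalar(t) else out


def rise_fall_auc(kp: KineticParams | tuple[float, float, float], endpoint: float) -> float:
    """Closed-form integral of the rise-and-fall curve over [0, endpoint]."""
    if isinstance(kp, KineticParams):
        c, k1, k2 = kp.c, kp.k1, kp.k2
    else:
        c, k1, k2 = kp
    T = float(endpoint)
    if abs(k1 - k2) <= _EQUAL_RATE_RTOL * max(abs(k1), abs(k2), 1.0):
        # int C t e^{-kt} = C (1 - (1+kT) e^{-kT}) / k^2
        k = k1
        if k == 0:
            return 0.5 * c * T * T
        return c * (1.0 - (1.0 + k * T) * math.exp(-k * T)) / (k * k)

    def _phase(k: float) -> float:
        if k == 0:
            return T
        return (1.0 - math.exp(-k * T)) / k

    return c / (k1 - k2) * (_phase(k2) - _phase(k1))


def _peak_value(c: float, k1: float, k2: float) -> float:
    if k2 <= 0:
        return c / k1  # plateau of the sustained curve
    tp = math.log(k1 / k2) / (k1 - k2)
    return eval_rise_fall((c, k1, k2), tp)


def amplitude_to_c(peak: float, k1: float, k2: float) -> float:
    """Amplitude scale C giving a curve whose maximum equals ``peak``."""
    return peak / _peak_value(1.0, k1, k2)


def trace_auc(trace: KineticTrace, endpoint: float | None = None) -> float:
    """Trapezoidal AUC of a trace over [0, endpoint] (signal * minutes).

    ``endpoint=None`` integrates the full recorded window.  An endpoint
    between samples is handled by linear interpolation of the signal.
    """
    t, y = trace.times, trace.signals
    if endpoint is None:
        endpoint = float(t[-1])
    if endpoint <= 0:
        raise ValueError("endpoint must be > 0")
    if endpoint > t[-1] + 1e-9:
        raise ValueError(f"endpoint {endpoint} min beyond trace range ({t[-1]} min)")
    endpoint = min(endpoint, float(t[-1]))
    keep = t <= endpoint + 1e-12
    tt, yy = t[keep], y[keep]
    if tt[-1] < endpoint:
        y_end = float(np.interp(endpoint, t, y))
        tt = np.append(tt, endpoint)
        yy = np.append(yy, y_end)
    return float(np.trapezoid(yy, tt))


def _initial_guesses(t: np.ndarray, y: np.ndarray, seed: int, n_extra: int) -> list[np.ndarray]:
    """Heuristic + randomized starts in (C, K2, dK) space with K1 = K2 + dK."""
    span = max(np.max(np.abs(y)), 1e-12)
    i_peak = int(np.argmax(np.abs(y)))
    t_peak = max(t[i_peak], t[1] if t.size > 1 else 1.0)
    starts = []
    # grid of rate-ratio guesses inverted from the time-to-peak identity
    for ratio in (2.0, 5.0, 20.0, 1000.0):
        k2 = math.log(ratio) / (t_peak * (ratio - 1.0))
        k1 = ratio * k2
        c = span / _peak_value(1.0, k1, k2)
        starts.append(np.array([c, k2, k1 - k2]))
    # sustained-curve guess (K2 ~ 0)
    k1 = 1.0 / t_peak
    starts.append(np.array([span * k1, 1e-6, k1]))
    rng = np.random.default_rng(seed)
    for _ in range(n_extra):
        k1 = 10.0 ** rng.uniform(-2, 1)
        k2 = k1 * rng.uniform(0.0, 0.9)
        c = span / _peak_value(1.0, k1, max(k2, 1e-12)) * rng.uniform(0.5, 2.0)
        starts.append(np.array([c * math.copysign(1.0, y[i_peak]), k2, k1 - k2]))
    return starts


def fit_rise_fall(trace: KineticTrace, n_starts: int = 20, seed: int = 0) -> KineticFit:
    """Least-squares fit of (C, K1, K2) to one trace, K1 > K2 >= 0 enforced.

    The fit is parameterized as (C, K2, dK = K1 - K2 > 0) so the rate
    ordering is a box constraint.  Traces with no dynamic range are flagged
    degenerate and returned without parameters; a stalled optimizer yields
    ``converged=False`` rather than an exception.
    """
    t, y = trace.times, trace.signals
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit the rise-and-fall model")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite signals in trace")
    if np.ptp(y) == 0.0:
        return KineticFit(None, None, 0.0, converged=False, degenerate=True,
                          n_points=t.size, message="constant trace, no kinetic signal")

    def resid(theta: np.ndarray) -> np.ndarray:
        c, k2, dk = theta
        return eval_rise_fall((c, k2 + dk, k2), t) - y

    scale = max(np.max(np.abs(y)), 1e-12)
    lb = np.array([-1e6 * scale, 0.0, 1e-9])
    ub = np.array([1e6 * scale, 50.0, 50.0])
    best = None
    n_ok = 0
    for x0 in _initial_guesses(t, y, seed, max(n_starts - 5, 0)):
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-12)
        except Exception:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return KineticFit(None, None, math.inf, converged=False, degenerate=False,
                          n_points=t.size, message="all optimizer starts failed")
    c, k2, dk = best.x
    k1 = k2 + dk
    params = KineticParams(c=float(c), k1=float(k1), k2=float(k2))
    rss = float(2.0 * best.cost)
    return KineticFit(params=params, t_half=params.t_half, rss=rss,
                      converged=bool(best.success), degenerate=False,
                      n_points=t.size, message=f"{n_ok} starts converged")
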