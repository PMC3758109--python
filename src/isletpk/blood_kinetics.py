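"""Biexponential blood-clearance model.

Prediction, nonlinear least-squares fitting of serial blood samples, and the
fraction-weighted half-life summary used to report multi-phase clearance as a
single number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "VALID_UNITS",
    "TimeActivityCurve",
    "BiexpDisposition",
    "FitResult",
    "biexp_predict",
    "weighted_half_life",
    "fit_biexp",
]

LN2 = math.log(2.0)

#: Closed vocabulary of concentration units accepted on time-activity tables.
VALID_UNITS = frozenset({"%ID/g", "%ID/kg", "Bq/g", "frac_c0"})


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled tracer concentration versus time for one tissue and subject.

    Times are minutes and must be strictly increasing; values are nonnegative
    activities in the declared unit.
    """

    times_min: np.ndarray
    values: np.ndarray
    unit: str
    tissue: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times_min and values must be 1-D")
        if len(t) != len(v):
            raise ValueError(
                f"length mismatch: {len(t)} times vs {len(v)} values"
            )
        if len(t) == 0:
            raise ValueError("time-activity curve must not be empty")
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(
                f"times_min must be strictly increasing (violated at index {bad})"
            )
        if np.any(v < 0):
            raise ValueError("values must be nonnegative")
        if self.unit not in VALID_UNITS:
            raise ValueError(
                f"unit {self.unit!r} not in accepted vocabulary {sorted(VALID_UNITS)}"
            )

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class BiexpDisposition:
    """Two-phase exponential disposition.

    ``scale_c0`` is the concentration at t=0; the fast and slow fractions must
    sum to one, and the fast half-life must be strictly smaller than the slow
    one. A single-phase disposition is expressed with ``frac_slow == 0`` and an
    infinite slow half-life (see :meth:`single_phase`).
    """

    scale_c0: float
    frac_fast: float
    t_half_fast_min: float
    frac_slow: float
    t_half_slow_min: float

    def __post_init__(self) -> None:
        if not (self.scale_c0 > 0):
            raise ValueError(f"scale_c0 must be positive, got {self.scale_c0!r}")
        if not (0.0 <= self.frac_fast <= 1.0 and 0.0 <= self.frac_slow <= 1.0):
            raise ValueError("phase fractions must lie in [0, 1]")
        if abs(self.frac_fast + self.frac_slow - 1.0) > 1e-9:
            raise ValueError(
                "frac_fast + frac_slow must equal 1, got "
                f"{self.frac_fast + self.frac_slow!r}"
            )
        if not (self.t_half_fast_min > 0):
            raise ValueError("t_half_fast_min must be positive")
        if not (self.t_half_slow_min > self.t_half_fast_min):
            raise ValueError(
                "t_half_fast_min must be strictly smaller than t_half_slow_min "
                f"(got {self.t_half_fast_min!r} vs {self.t_half_slow_min!r})"
            )

    @classmethod
    def single_phase(cls, scale_c0: float, t_half_min: float) -> "BiexpDisposition":
        """A monoexponential disposition (all mass in the fast phase)."""
        return cls(
            scale_c0=scale_c0,
            frac_fast=1.0,
            t_half_fast_min=t_half_min,
            frac_slow=0.0,
            t_half_slow_min=math.inf,
        )


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares curve fit."""

    params: BiexpDisposition
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    converged: bool
    degenerate: bool = False
    message: str = ""


def biexp_predict(params: BiexpDisposition, t) -> np.ndarray | float:
    """Evaluate the biexponential decay curve at time(s) ``t`` (minutes).

    ``c0 * (f_fast * 2**(-t/t_fast) + f_slow * 2**(-t/t_slow))``; strictly
    decreasing and convex in ``t`` for valid parameters. Negative times are
    rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    fast = params.frac_fast * np.exp2(-t_arr / params.t_half_fast_min)
    if params.frac_slow > 0:
        slow = params.frac_slow * np.exp2(-t_arr / params.t_half_slow_min)
    else:
        slow = 0.0
    out = params.scale_c0 * (fast + slow)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def weighted_half_life(params: BiexpDisposition) -> float:
    """Fraction-weighted arithmetic mean of the phase half-lives, in minutes.

    ``f_fast * t_fast + f_slow * t_slow``; zero-fraction phases contribute
    nothing (so a single-phase disposition returns its only half-life).
    """
    total = 0.0
    if params.frac_fast > 0:
        total += params.frac_fast * params.t_half_fast_min
    if params.frac_slow > 0:
        total += params.frac_slow * params.t_half_slow_min
    return total


# ---------------------------------------------------------------------------
# fitting


def _peel_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Log-linear curve-peeling initial guess ``(c0, f_fast, th_fast, th_slow)``.

    Fits the terminal slope on the last third of the samples, strips that
    phase, and fits the remainder. Falls back to generic ratios whenever a
    phase cannot be resolved (e.g. effectively monoexponential data).
    """
    n = len(t)
    n_tail = max(3, n // 3)
    t_tail, y_tail = t[-n_tail:], y[-n_tail:]
    ok = y_tail > 0
    th_slow = None
    a_slow = None
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(t_tail[ok], np.log(y_tail[ok]), 1)
        if slope < 0:
            th_slow = LN2 / -slope
            a_slow = math.exp(intercept)
    if th_slow is None:
        th_slow = max(t[-1], 1.0)
        a_slow = max(y[-1], 1e-12)

    head = y[:-n_tail] - a_slow * np.exp(-LN2 * t[:-n_tail] / th_slow)
    t_head = t[:-n_tail]
    ok = head > 0
    th_fast = None
    a_fast = None
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(t_head[ok], np.log(head[ok]), 1)
        if slope < 0:
            th_fast = LN2 / -slope
            a_fast = math.exp(intercept)
    if th_fast is None or th_fast >= th_slow:
        th_fast = th_slow / 4.0
        a_fast = a_slow
    c0 = a_fast + a_slow
    f_fast = min(max(a_fast / c0, 0.05), 0.95)
    return c0, f_fast, th_fast, th_slow


def _unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
    log_c0, logit_f, log_th1, log_th2 = theta
    c0 = math.exp(log_c0)
    f = 1.0 / (1.0 + math.exp(-logit_f))
    return c0, f, math.exp(log_th1), math.exp(log_th2)


def fit_biexp(
    tac: TimeActivityCurve,
    weighting: str = "uniform",
    init: Optional[BiexpDisposition] = None,
) -> FitResult:
    """Fit a biexponential decay curve to serial blood samples.

    Optimizes in log space for the half-lives and C0 and logit space for the
    fast fraction, enforcing positivity; phases are ordered by half-life after
    the fit. With ``weighting="proportional"`` residuals are divided by the
    observed value (1/y weighting of residuals, i.e. 1/y^2 on squared errors);
    the default is unweighted. R^2 is computed under the same weighting.

    At least five samples are required. Non-convergence is reported through
    ``FitResult.converged``; a vanishing phase fraction or indistinguishable
    half-lives set ``FitResult.degenerate``.
    """
    if len(tac) < 5:
        raise ValueError(f"need at least 5 samples to fit, got {len(tac)}")
    if weighting not in ("uniform", "proportional"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t = tac.times_min
    y = tac.values
    if weighting == "proportional":
        w = 1.0 / np.maximum(y, np.max(y) * 1e-6)
    else:
        w = np.ones_like(y)

    if init is not None:
        c0, f, th1, th2 = (
            init.scale_c0,
            min(max(init.frac_fast, 1e-6), 1 - 1e-6),
            init.t_half_fast_min,
            init.t_half_slow_min if math.isfinite(init.t_half_slow_min) else 4 * init.t_half_fast_min,
        )
    else:
        c0, f, th1, th2 = _peel_init(t, y)
    theta0 = np.array(
        [math.log(c0), math.log(f / (1 - f)), math.log(th1), math.log(th2)]
    )

    def resid(theta: np.ndarray) -> np.ndarray:
        c0_, f_, th1_, th2_ = _unpack(theta)
        pred = c0_ * (f_ * np.exp2(-t / th1_) + (1 - f_) * np.exp2(-t / th2_))
        return w * (pred - y)

    sol = least_squares(
        resid, theta0, ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=20000
    )
    c0_f, f_f, th1_f, th2_f = _unpack(sol.x)
    # order phases: fast = smaller half-life
    if th1_f > th2_f:
        th1_f, th2_f = th2_f, th1_f
        f_f = 1.0 - f_f

    degenerate = (
        f_f < 1e-3 or f_f > 1 - 1e-3 or th2_f / th1_f < 1.001
    )
    if degenerate:
        # collapse onto a clean single-phase disposition for reporting
        th_only = th1_f if f_f >= 0.5 else th2_f
        params = BiexpDisposition.single_phase(c0_f, th_only)
    else:
        params = BiexpDisposition(
            scale_c0=c0_f,
            frac_fast=f_f,
            t_half_fast_min=th1_f,
            frac_slow=1.0 - f_f,
            t_half_slow_min=th2_f,
        )

    res = resid(sol.x)
    ybar = np.sum(w**2 * y) / np.sum(w**2)
    ss_tot = float(np.sum((w * (y - ybar)) ** 2))
    ss_res = float(np.sum(res**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        params=params,
        r_squared=r2,
        residuals=res / w,
        converged=bool(sol.success),
        degenerate=degenerate,
        message=sol.message,
    )
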