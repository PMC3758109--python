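"""Two-compartment (mammillary) plasma disposition.

Micro rate constants <-> macro biexponential parameters, closed-form bolus
and constant-infusion solutions, and least-squares fitting of infusion-phase
concentration data. Elimination occurs from the central compartment only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .blood_kinetics import (
    LN2,
    BiexpDisposition,
    FitResult,
    TimeActivityCurve,
)

__all__ = [
    "TwoCompParams",
    "InfusionProtocol",
    "NonIdentifiableError",
    "macro_from_micro",
    "micro_from_macro",
    "bolus_concentration",
    "infusion_concentration",
    "fit_two_compartment",
]


class NonIdentifiableError(ValueError):
    """Raised when the sampled data cannot constrain the model parameters."""


@dataclass(frozen=True)
class TwoCompParams:
    """Micro rate constants of a two-compartment model.

    ``k10`` eliminates from the central compartment, ``k12``/``k21`` exchange
    with the peripheral compartment (all per minute); ``v_central`` is the
    central distribution volume in whatever unit the concentrations use
    (defaults to 1 for concentrations expressed as fraction of C0).
    """

    k10: float
    k12: float
    k21: float
    v_central: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k10 > 0):
            raise ValueError(f"k10 must be positive, got {self.k10!r}")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("k12 and k21 must be nonnegative")
        if not (self.v_central > 0):
            raise ValueError(f"v_central must be positive, got {self.v_central!r}")


@dataclass(frozen=True)
class InfusionProtocol:
    """Constant-rate infusion over ``[t_start, t_end)`` minutes.

    ``t_end=None`` means the infusion is ongoing (open-ended).
    """

    rate: float
    t_start: float = 0.0
    t_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be nonnegative, got {self.rate!r}")
        end = math.inf if self.t_end is None else self.t_end
        if not (self.t_start < end):
            raise ValueError(
                f"t_start must precede t_end, got {self.t_start!r} >= {self.t_end!r}"
            )


def _eigenvalues(p: TwoCompParams) -> tuple[float, float]:
    """Hybrid rate constants (alpha, beta), alpha >= beta >= 0."""
    s = p.k10 + p.k12 + p.k21
    prod = p.k10 * p.k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


def _bolus_coeffs(p: TwoCompParams) -> tuple[float, float, float, float]:
    """``(A, alpha, B, beta)`` of the unit-bolus central concentration.

    ``C(t) = (1/v_central) * (A exp(-alpha t) + B exp(-beta t))`` with
    ``A + B = 1``.
    """
    alpha, beta = _eigenvalues(p)
    if alpha == beta:
        raise NonIdentifiableError(
            "repeated eigenvalue: the two phases are indistinguishable"
        )
    a = (alpha - p.k21) / (alpha - beta)
    b = (p.k21 - beta) / (alpha - beta)
    return a, alpha, b, beta


def macro_from_micro(p: TwoCompParams) -> BiexpDisposition:
    """Macro biexponential disposition of a unit bolus dose.

    The phase rates satisfy ``alpha + beta = k10 + k12 + k21`` and
    ``alpha * beta = k10 * k21``; fractions come from the residue
    coefficients of the bolus solution. The alpha phase maps to the fast
    component. ``scale_c0`` is ``1 / v_central`` (unit dose).

    A peripheral trap (``k21 == 0`` with ``k12 > 0``) has no terminal return
    phase and is reported as a single-phase disposition with a warning.
    """
    a, alpha, b, beta = _bolus_coeffs(p)
    c0 = 1.0 / p.v_central
    if beta <= 0.0 or b <= 0.0:
        if p.k21 == 0.0 and p.k12 > 0.0:
            warnings.warn(
                "k21 = 0 with k12 > 0: peripheral compartment is a trap; "
                "returning a single-phase disposition",
                stacklevel=2,
            )
        return BiexpDisposition.single_phase(c0, LN2 / alpha)
    return BiexpDisposition(
        scale_c0=c0,
        frac_fast=a,
        t_half_fast_min=LN2 / alpha,
        frac_slow=b,
        t_half_slow_min=LN2 / beta,
    )


def micro_from_macro(
    d: BiexpDisposition, v_central: Optional[float] = None
) -> TwoCompParams:
    """Invert :func:`macro_from_micro`.

    Requires two genuinely distinct phases (both fractions nonzero, finite
    half-lives). ``v_central`` defaults to ``1 / scale_c0`` so that the
    roundtrip through :func:`macro_from_micro` is the identity.
    """
    if d.frac_fast <= 0 or d.frac_slow <= 0 or not math.isfinite(d.t_half_slow_min):
        raise NonIdentifiableError(
            "micro_from_macro requires two distinct phases with nonzero fractions"
        )
    alpha = LN2 / d.t_half_fast_min
    beta = LN2 / d.t_half_slow_min
    if abs(alpha - beta) / alpha < 1e-12:
        raise NonIdentifiableError("equal half-lives are non-identifiable")
    k21 = d.frac_fast * beta + d.frac_slow * alpha
    k10 = alpha * beta / k21
    k12 = alpha + beta - k10 - k21
    if k12 < 0:
        k12 = max(k12, 0.0)  # clip roundoff
    v = v_central if v_central is not None else 1.0 / d.scale_c0
    return TwoCompParams(k10=k10, k12=k12, k21=k21, v_central=v)


def bolus_concentration(p: TwoCompParams, dose: float, t) -> np.ndarray | float:
    """Central-compartment concentration after an instantaneous bolus."""
    if not (dose > 0):
        raise ValueError(f"dose must be positive, got {dose!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    a, alpha, b, beta = _bolus_coeffs(p)
    out = (dose / p.v_central) * (
        a * np.exp(-alpha * t_arr) + b * np.exp(-beta * t_arr)
    )
    return float(out) if t_arr.ndim == 0 else out


def _infusion_step(p: TwoCompParams, rate: float, tau: np.ndarray) -> np.ndarray:
    """Concentration response to an infusion switched on at tau = 0."""
    a, alpha, b, beta = _bolus_coeffs(p)
    tau = np.maximum(tau, 0.0)
    term_a = a * -np.expm1(-alpha * tau) / alpha
    if beta > 0:
        term_b = b * -np.expm1(-beta * tau) / beta
    else:
        term_b = b * tau  # beta -> 0 limit
    return (rate / p.v_central) * (term_a + term_b)


def infusion_concentration(
    p: TwoCompParams, proto: InfusionProtocol, t
) -> np.ndarray | float:
    """Central concentration under a constant-rate infusion.

    Superposition of the step response switched on at ``t_start`` and (for a
    finite infusion) an equal negative step at ``t_end``. Under an ongoing
    infusion the long-time limit is the steady state
    ``rate / (k10 * v_central)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    c = _infusion_step(p, proto.rate, t_arr - proto.t_start)
    if proto.t_end is not None:
        c = c - _infusion_step(p, proto.rate, t_arr - proto.t_end)
    return float(c) if t_arr.ndim == 0 else c


_DEFAULT_STARTS = (
    (0.05, 0.5, 0.2),
    (0.1, 0.1, 0.1),
    (0.5, 1.0, 0.5),
    (0.01, 0.05, 0.02),
)


def fit_two_compartment(
    data: TimeActivityCurve,
    proto: InfusionProtocol,
    v_central: float = 1.0,
    init: Optional[TwoCompParams] = None,
) -> tuple[TwoCompParams, FitResult]:
    """Least-squares fit of the micro rate constants to infusion-phase data.

    ``v_central`` is held fixed (the concentration scale and the infusion
    rate fix it jointly with the rates; by default concentrations are treated
    as already normalized). Requires at least six samples with real dynamics:
    a curve sampled only at steady state raises
    :class:`NonIdentifiableError`. Several deterministic multi-starts guard
    against local minima; the best final cost wins.
    """
    if len(data) < 6:
        raise ValueError(f"need at least 6 samples to fit, got {len(data)}")
    t = data.times_min
    y = data.values
    spread = (y.max() - y.min()) / max(y.max(), 1e-300)
    if spread < 1e-6:
        raise NonIdentifiableError(
            "samples show no dynamics (steady-state only); rates are not identifiable"
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        k10, k12, k21 = np.exp(theta)
        p = TwoCompParams(k10=k10, k12=k12, k21=k21, v_central=v_central)
        return infusion_concentration(p, proto, t) - y

    starts = []
    if init is not None:
        starts.append((init.k10, init.k12, init.k21))
    starts.extend(_DEFAULT_STARTS)

    best = None
    for s in starts:
        sol = least_squares(
            resid,
            np.log(np.asarray(s)),
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=20000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    k10, k12, k21 = np.exp(best.x)
    params = TwoCompParams(k10=k10, k12=k12, k21=k21, v_central=v_central)

    res = resid(best.x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 1.0
    fit = FitResult(
        params=macro_from_micro(params),
        r_squared=r2,
        residuals=res,
        converged=bool(best.success),
        message=best.message,
    )
    return params, fit
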