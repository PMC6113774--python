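"""Kinetics of dermal maturation: the PF/QF/ECM negative-feedback ODE system.

The model tracks proliferating fibroblasts (PF), quiescent fibroblasts (QF)
and extracellular matrix (ECM).  PF self-replicate at net rate ``beta`` and
interconvert with QF (rates ``k2``/``km2``); QF deposit ECM (``k3``) and are
lost at rate ``k6``; ECM turns over at rate ``k7``.  The defining feature is
a catalytic negative feedback, PF + ECM -> QF + ECM: matrix contact drives
proliferating cells into quiescence at rate ``k4 * ECM``, so the tissue
shuts down its own proliferation as matrix accumulates.

    dPF/dt  = beta*PF + km2*QF - k4*ECM*PF
    dQF/dt  = k2*PF - km2*QF + k4*ECM*PF - k6*QF
    dECM/dt = k3*QF - k7*ECM

The system has a unique non-trivial fixed point with a closed form, whose
local stability (all Jacobian eigenvalues with negative real part) is used
as a hard filter during parameter fitting: only parameterisations that
yield a stable adult dermis are admissible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import FitSolution, KineticParameters

__all__ = [
    "KineticParameters",
    "SystemState",
    "Trajectory",
    "FixedPoint",
    "derivatives",
    "fixed_point",
    "jacobian",
    "is_stable",
    "simulate",
    "pf_percentage",
]

#: denominator guard for the PF percentage of an empty compartment
PF_PERCENT_EPS = 1e-12
#: default tolerance on eigenvalue real parts for the stability verdict
STABILITY_TOL = 1e-8

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class SystemState:
    """Amounts of the three model species at one instant."""

    pf: float
    qf: float
    ecm: float

    def __post_init__(self) -> None:
        if self.pf < 0 or self.qf < 0 or self.ecm < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.pf, self.qf, self.ecm], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: times (days) and the matching states."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3), columns PF, QF, ECM

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if states.shape != (times.size, 3):
            raise ValueError("states must have shape (len(times), 3)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def pf(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def qf(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def ecm(self) -> np.ndarray:
        return self.states[:, 2]

    def pf_percent(self) -> np.ndarray:
        """PF as a percentage of all fibroblasts at each time point."""
        tot = self.pf + self.qf
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(tot < PF_PERCENT_EPS, 0.0, 100.0 * self.pf / np.maximum(tot, PF_PERCENT_EPS))
        return pct


@dataclass(frozen=True)
class FixedPoint:
    """The non-trivial stationary state, its eigenvalues and a stability verdict.

    ``exists`` is False for degenerate parameter sets (``k4 = 0``, ``k3 = 0``,
    ``k6 = 0`` or ``beta + k2 <= 0``) for which no finite positive fixed
    point exists; ``state`` is then None.
    """

    exists: bool
    state: Optional[SystemState]
    eigen_real_parts: Optional[np.ndarray]
    stable: bool


class SolverError(RuntimeError):
    """Adaptive integration failed; carries the solver's diagnostic message."""


def derivatives(state, params: KineticParameters):
    """Right-hand side of the maturation model: (dPF, dQF, dECM) per day.

    ``state`` may be a :class:`SystemState` or any 3-sequence (PF, QF, ECM).
    """
    if isinstance(state, SystemState):
        pf, qf, ecm = state.pf, state.qf, state.ecm
    else:
        pf, qf, ecm = state
    b, k2, km2, k3, k4, k6, k7 = params.as_tuple()
    dpf = b * pf + km2 * qf - k4 * ecm * pf
    dqf = k2 * pf - km2 * qf + k4 * ecm * pf - k6 * qf
    decm = k3 * qf - k7 * ecm
    return (dpf, dqf, decm)


def fixed_point(params: KineticParameters, tol: float = STABILITY_TOL) -> FixedPoint:
    """Closed-form non-trivial fixed point with its stability classification.

    PF* = k7*(km2*(beta+k2) + beta*k6) / (k3*k4*(beta+k2))
    QF* = k7*(km2*(beta+k2) + beta*k6) / (k3*k4*k6)
    ECM* = (km2*(beta+k2) + beta*k6) / (k4*k6)

    Without the matrix feedback (k4 = 0) the only steady state is the
    origin — the feedback is what sustains a finite adult composition.
    """
    b, k2, km2, k3, k4, k6, k7 = params.as_tuple()
    if k4 == 0 or k3 == 0 or k6 == 0 or (b + k2) <= 0:
        return FixedPoint(exists=False, state=None, eigen_real_parts=None, stable=False)
    num = km2 * (b + k2) + b * k6
    if num <= 0:
        return FixedPoint(exists=False, state=None, eigen_real_parts=None, stable=False)
    pf_star = k7 * num / (k3 * k4 * (b + k2))
    qf_star = k7 * num / (k3 * k4 * k6)
    ecm_star = num / (k4 * k6)
    state = SystemState(pf_star, qf_star, ecm_star)
    jac = _rhs_jacobian(state.as_array(), params)
    eig = np.linalg.eigvals(jac)
    real_parts = np.sort(eig.real)
    stable = bool(np.max(real_parts) < -tol)
    return FixedPoint(exists=True, state=state, eigen_real_parts=real_parts, stable=stable)


def _rhs_jacobian(y: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Jacobian of the RHS at an arbitrary state (PF, QF, ECM)."""
    pf, qf, ecm = y
    b, k2, km2, k3, k4, k6, k7 = params.as_tuple()
    return np.array(
        [
            [b - k4 * ecm, km2, -k4 * pf],
            [k2 + k4 * ecm, -km2 - k6, k4 * pf],
            [0.0, k3, -k7],
        ]
    )


def jacobian(params: KineticParameters) -> np.ndarray:
    """Jacobian of the model evaluated at the non-trivial fixed point.

    Computed as the general RHS Jacobian at the closed-form fixed-point
    state rather than from a transcribed matrix, which avoids any
    typesetting ambiguity in the printed form.
    """
    fp = fixed_point(params)
    if not fp.exists:
        raise ValueError("no finite positive fixed point exists for these parameters")
    return _rhs_jacobian(fp.state.as_array(), params)


def is_stable(params: KineticParameters, tol: float = STABILITY_TOL):
    """Stability verdict and eigenvalue real parts at the fixed point.

    Returns ``(stable, eigen_real_parts)``; raises if the fixed point does
    not exist.
    """
    fp = fixed_point(params, tol=tol)
    if not fp.exists:
        raise ValueError("no finite positive fixed point exists for these parameters")
    return fp.stable, fp.eigen_real_parts


def simulate(
    solution: FitSolution,
    t_eval: Sequence[float],
    rtol: float = _RTOL,
    atol: float = _ATOL,
    y0: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Integrate the maturation model and sample it at ``t_eval`` (days).

    Uses an adaptive explicit Runge-Kutta scheme (the system is non-stiff at
    the published parameter scales).  Tiny negative excursions below
    ``atol`` are clipped to zero so returned states are valid amounts.
    ``y0`` overrides the solution's initial state (used e.g. to start at the
    fixed point).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval.size == 0:
        raise ValueError("t_eval must be a non-empty 1-D array")
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if t_eval[0] < solution.t0:
        raise ValueError(f"t_eval must start at or after t0 = {solution.t0}")
    if y0 is None:
        y0 = [solution.pf0, solution.qf0, solution.ecm0]
    y0 = np.asarray(y0, dtype=float)
    params = solution.params

    def rhs(t, y):
        return derivatives(y, params)

    def jac(t, y):
        return _rhs_jacobian(y, params)

    t_span = (solution.t0, float(t_eval[-1]))
    res = solve_ivp(
        rhs, t_span, y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=False,
    )
    if not res.success:
        raise SolverError(f"integration failed: {res.message}")
    states = res.y.T.copy()
    # clip round-off level negatives; anything larger is a genuine failure
    mask = (states < 0) & (states > -100 * atol - 1e-30)
    states[mask] = 0.0
    if np.any(states < 0):
        raise SolverError("integration produced substantially negative amounts")
    return Trajectory(times=t_eval, states=states)


def pf_percentage(pf: float, qf: float) -> float:
    """Proliferating fibroblasts as a percentage of all fibroblasts.

    Returns 0 for an (essentially) empty fibroblast compartment, the
    convention needed for a freshly cleared wound bed.
    """
    if pf < 0 or qf < 0:
        raise ValueError("pf and qf must be non-negative")
    tot = pf + qf
    if tot < PF_PERCENT_EPS:
        return 0.0
    return 100.0 * pf / tot
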