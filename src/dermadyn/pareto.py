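"""Stability-constrained Monte Carlo Pareto fit of the maturation model.

Fitting the seven rate constants and two free initial conditions to the two
measured time courses (PF% and ECM%) is a multi-objective problem: the mean
square deviation from each dataset is its own objective, and there is no
canonical way to weight them against each other.  The procedure therefore

1. draws random parameter/initial-condition vectors within broad ranges,
2. keeps only draws whose non-trivial fixed point exists and is linearly
   stable (an unstable adult dermis is biologically inadmissible),
3. scores each accepted draw by the pair (msePF, mseECM),
4. extracts the Pareto front of non-dominated objective pairs, and
5. selects one front member (by default the knee point of the normalised
   front).

Because Pareto dominance is invariant to monotone rescaling of either
objective, no relative weighting of the two datasets is needed.

Plain uniform sampling of the nine-dimensional search box essentially
never lands a draw that fits both datasets at once: the well-fitting region
is a thin, strongly correlated valley.  The sampler is therefore iterative,
in the spirit of interval-contraction Monte Carlo multi-objective
calibration: the draw budget is spent over several rounds, and after each
round the per-parameter sampling intervals contract around the current
balanced elite (the candidates with the smallest worse-of-the-two
deviations -- both objectives live on the same percent^2 scale, so the
Chebyshev score needs no weighting).  Part of each round perturbs elite
members locally, which lets the search follow correlated directions an
axis-aligned box cannot express, and a small fraction of every round keeps
sampling the full original box so the contraction cannot permanently lock
onto a secondary basin.  Every evaluated candidate, from every round,
enters the final Pareto front.  With one round the procedure reduces to
plain uniform Monte Carlo sampling.

The bulk objective evaluation runs all stable candidates through a
vectorised fixed-step RK4 integrator (batched over candidates), with
automatic step refinement for the minority of draws whose kinetics are too
fast for the base step; the handful of draws that still overflow are
counted as failed and excluded.  The scalar :func:`mse_pair` entry point
uses the adaptive solver and serves as the reference the batch evaluator is
validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import FitSolution, KineticParameters, ObservedDataset
from .maturation import (
    PF_PERCENT_EPS,
    STABILITY_TOL,
    SolverError,
    fixed_point,
    simulate,
)

__all__ = [
    "SamplingRanges",
    "ParetoCandidate",
    "ParetoFront",
    "FitResult",
    "default_ranges",
    "sample_candidate",
    "mse_pair",
    "pareto_front",
    "select_solution",
    "fit",
]

_PARAM_ORDER = ("beta", "k2", "km2", "k3", "k4", "k6", "k7", "pf0", "qf0")


@dataclass(frozen=True)
class SamplingRanges:
    """Per-parameter sampling bounds and scale (``linear`` or ``log``).

    ``bounds`` maps each of beta, k2, km2, k3, k4, k6, k7, pf0, qf0 to a
    ``(lo, hi, scale)`` triple.  ``lo == hi`` collapses that parameter to a
    point (useful for degenerate/diagnostic sampling); log-scale bounds must
    be positive.
    """

    bounds: dict

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name}")
            lo, hi, scale = self.bounds[name]
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper")
            if scale not in ("linear", "log"):
                raise ValueError(f"{name}: unknown scale {scale!r}")
            if scale == "log" and lo <= 0:
                raise ValueError(f"{name}: log-scale bounds must be > 0")

    def arrays(self):
        lo = np.array([self.bounds[n][0] for n in _PARAM_ORDER])
        hi = np.array([self.bounds[n][1] for n in _PARAM_ORDER])
        is_log = np.array([self.bounds[n][2] == "log" for n in _PARAM_ORDER])
        return lo, hi, is_log


def default_ranges() -> SamplingRanges:
    """Default search box: rates log-uniform on [1e-3, 3]; beta uniform on
    [0, 1]; initial fibroblast amounts uniform on (0, 1].

    The box brackets the published fit with at least a decade of margin on
    every rate.
    """
    b: dict = {}
    for name in ("k2", "km2", "k3", "k4", "k6", "k7"):
        b[name] = (1e-3, 3.0, "log")
    b["beta"] = (0.0, 1.0, "linear")
    b["pf0"] = (0.0, 1.0, "linear")  # open at 0 by construction of the draw
    b["qf0"] = (0.0, 1.0, "linear")
    return SamplingRanges(b)


def _transform(u: np.ndarray, ranges: SamplingRanges) -> np.ndarray:
    """Map uniforms in [0,1) (shape (..., 9)) to parameter values.

    Linear parameters map to ``hi - u*(hi-lo)`` so the draw lies in
    (lo, hi], keeping initial amounts strictly positive; log parameters are
    log-uniform on [lo, hi].
    """
    lo, hi, is_log = ranges.arrays()
    out = np.empty_like(u)
    lin = ~is_log
    out[..., lin] = hi[lin] - u[..., lin] * (hi[lin] - lo[lin])
    llo, lhi = np.log(lo[is_log]), np.log(hi[is_log])
    out[..., is_log] = np.exp(llo + u[..., is_log] * (lhi - llo))
    return out


def _to_solution(row: np.ndarray) -> FitSolution:
    params = KineticParameters(*[float(v) for v in row[:7]])
    return FitSolution(params=params, pf0=float(row[7]), qf0=float(row[8]))


def sample_candidate(rng: np.random.Generator, ranges: Optional[SamplingRanges] = None) -> FitSolution:
    """Draw one random candidate (9 uniforms consumed in a fixed order).

    ECM(t0) is fixed at zero and t0 at day 10.5; only the seven rates and
    the two fibroblast initial amounts are randomised.
    """
    if ranges is None:
        ranges = default_ranges()
    u = rng.random(9)
    return _to_solution(_transform(u, ranges))


# ---------------------------------------------------------------------------
# objectives


def mse_pair(
    solution: FitSolution,
    pf_data: ObservedDataset,
    ecm_data: ObservedDataset,
) -> tuple[float, float]:
    """Mean square deviations of the model from the two datasets.

    The model PF percentage (100*PF/(PF+QF)) is compared to the PF% data;
    model ECM is compared to the ECM% data directly (the fitted steady
    state lies on the percent scale).  Uses the adaptive integrator.
    """
    times = np.union1d(pf_data.times, ecm_data.times)
    if times[0] < solution.t0:
        raise ValueError("data precede the model's initial time")
    if times[0] > solution.t0:
        times = np.concatenate([[solution.t0], times])
    traj = simulate(solution, times)
    t_index = {t: i for i, t in enumerate(traj.times)}
    pf_pct = traj.pf_percent()
    pf_pred = np.array([pf_pct[t_index[t]] for t in pf_data.times])
    ecm_pred = np.array([traj.ecm[t_index[t]] for t in ecm_data.times])
    mse_pf = float(np.mean((pf_pred - np.asarray(pf_data.values)) ** 2))
    mse_ecm = float(np.mean((ecm_pred - np.asarray(ecm_data.values)) ** 2))
    return mse_pf, mse_ecm


def _batch_rk4(
    theta: np.ndarray,
    y0: np.ndarray,
    offsets: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 for a batch of candidates, sampled at time offsets.

    ``theta``: (n, 7) rate constants; ``y0``: (n, 3) initial states;
    ``offsets``: sorted sample times relative to t0.  States are clamped to
    be non-negative after every step (the flow is forward-invariant on the
    positive octant; the clamp only removes round-off excursions and stops
    sign-flip blow-ups of diverging steps).  Returns ``(samples, ok)`` with
    samples of shape (n, len(offsets), 3); rows with non-finite or
    overflowing trajectories have ok=False.
    """
    n = theta.shape[0]
    b, k2, km2, k3, k4, k6, k7 = (theta[:, j] for j in range(7))

    def rhs(y):
        pf, qf, ecm = y[:, 0], y[:, 1], y[:, 2]
        conv = k4 * ecm * pf
        dpf = b * pf + km2 * qf - conv
        dqf = k2 * pf - km2 * qf + conv - k6 * qf
        decm = k3 * qf - k7 * ecm
        return np.stack([dpf, dqf, decm], axis=1)

    n_steps = int(round(offsets[-1] / dt))
    # nearest-step sampling with linear interpolation for off-grid offsets
    pos = offsets / dt
    k_lo = np.clip(np.floor(pos + 1e-9).astype(int), 0, n_steps)
    frac = pos - k_lo
    want = {}
    for j, k in enumerate(k_lo):
        want.setdefault(int(k), []).append(j)
        if frac[j] > 1e-9:
            want.setdefault(int(k) + 1, []).append(~j)  # ~j marks "upper bracket"

    samples_lo = np.zeros((n, offsets.size, 3))
    samples_hi = np.zeros((n, offsets.size, 3))
    ok = np.ones(n, dtype=bool)
    y = y0.copy()

    def record(step, ycur):
        for j in want.get(step, ()):
            if j >= 0:
                samples_lo[:, j, :] = ycur
            else:
                samples_hi[:, ~j, :] = ycur

    with np.errstate(all="ignore"):
        record(0, y)
        for step in range(1, n_steps + 1):
            k1 = rhs(y)
            k2_ = rhs(y + 0.5 * dt * k1)
            k3_ = rhs(y + 0.5 * dt * k2_)
            k4_ = rhs(y + dt * k3_)
            y = y + (dt / 6.0) * (k1 + 2 * k2_ + 2 * k3_ + k4_)
            np.maximum(y, 0.0, out=y)
            if step % 8 == 0 or step == n_steps:
                bad = ~np.all(np.isfinite(y), axis=1) | (np.max(y, axis=1) > 1e10)
                if np.any(bad & ok):
                    ok &= ~bad
                    y[~ok] = 0.0
            record(step, y)
    has_hi = frac > 1e-9
    samples = samples_lo.copy()
    if np.any(has_hi):
        w = frac[has_hi]
        samples[:, has_hi, :] = (1 - w[None, :, None]) * samples_lo[:, has_hi, :] + w[
            None, :, None
        ] * samples_hi[:, has_hi, :]
    return samples, ok


def _batch_objectives(
    values: np.ndarray,
    y0: np.ndarray,
    pf_data: ObservedDataset,
    ecm_data: ObservedDataset,
    t0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(msePF, mseECM, ok) for a batch of candidates (rows of ``values``).

    Integrates with base step 1/16 day and re-integrates candidates that
    overflow with steps 1/256 and 1/2048 before declaring them failed.
    """
    n = values.shape[0]
    times = np.union1d(pf_data.times, ecm_data.times)
    offsets = times - t0
    pf_idx = np.searchsorted(times, pf_data.times)
    ecm_idx = np.searchsorted(times, ecm_data.times)
    pf_obs = np.asarray(pf_data.values)
    ecm_obs = np.asarray(ecm_data.values)

    mse_pf = np.full(n, np.inf)
    mse_ecm = np.full(n, np.inf)
    ok_all = np.zeros(n, dtype=bool)
    todo = np.arange(n)
    for dt in (1.0 / 16, 1.0 / 256, 1.0 / 2048):
        if todo.size == 0:
            break
        samples, ok = _batch_rk4(values[todo, :7], y0[todo], offsets, dt)
        done = todo[ok]
        if done.size:
            s = samples[ok]
            pf, qf, ecm = s[:, :, 0], s[:, :, 1], s[:, :, 2]
            tot = pf + qf
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(tot < PF_PERCENT_EPS, 0.0, 100.0 * pf / np.maximum(tot, PF_PERCENT_EPS))
            mse_pf[done] = np.mean((pct[:, pf_idx] - pf_obs) ** 2, axis=1)
            mse_ecm[done] = np.mean((ecm[:, ecm_idx] - ecm_obs) ** 2, axis=1)
            ok_all[done] = True
        todo = todo[~ok]
    return mse_pf, mse_ecm, ok_all


# ---------------------------------------------------------------------------
# Pareto machinery


def pareto_front(pairs: Sequence[tuple[float, float]]) -> list[int]:
    """Indices of the non-dominated objective pairs, ascending in the first
    objective.

    ``a`` dominates ``b`` iff a.mse_pf <= b.mse_pf and a.mse_ecm <= b.mse_ecm
    with at least one inequality strict; identical pairs do not dominate
    each other and are all retained.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        return []
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (mse_pf, mse_ecm)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("objective pairs must be finite")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    front: list[int] = []
    best_ecm_before = math.inf  # min ecm among strictly smaller mse_pf
    i = 0
    m = order.size
    while i < m:
        j = i
        pf_val = arr[order[i], 0]
        while j < m and arr[order[j], 0] == pf_val:
            j += 1
        group = order[i:j]
        gmin = arr[group, 1].min()
        if gmin < best_ecm_before:
            front.extend(int(g) for g in group if arr[g, 1] == gmin)
        best_ecm_before = min(best_ecm_before, gmin)
        i = j
    front.sort(key=lambda idx: (arr[idx, 0], arr[idx, 1]))
    return front


@dataclass(frozen=True)
class ParetoCandidate:
    """A sampled parameterisation with its objective pair and stability flag."""

    solution: FitSolution
    mse_pf: float
    mse_ecm: float
    stable: bool


@dataclass(frozen=True)
class ParetoFront:
    """The non-dominated set of a Monte Carlo fit, plus sampling bookkeeping.

    ``n_failed`` counts stable candidates whose integration overflowed at
    every step size and that were therefore excluded from scoring.
    """

    members: tuple[ParetoCandidate, ...]
    n_sampled: int
    n_stable: int
    seed: int
    n_failed: int = 0

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    def objective_pairs(self) -> np.ndarray:
        return np.array([[m.mse_pf, m.mse_ecm] for m in self.members])


@dataclass(frozen=True)
class FitResult:
    front: ParetoFront
    selected: Optional[ParetoCandidate]


def select_solution(front: ParetoFront, policy: str = "balanced") -> ParetoCandidate:
    """Pick one front member.

    ``balanced`` (default): minimiser of max(msePF, mseECM) -- the two
    objectives share the percent^2 scale, so the worse of the two is a
    meaningful summary and is robust to extreme trade-off members that
    stretch a normalised score.  ``knee``: minimiser of the sum of min-max
    normalised objectives.  ``min_pf`` / ``min_ecm``: the extreme member
    for that objective.  Ties break by smaller msePF, then smaller k4.
    """
    if front.is_empty:
        raise ValueError("cannot select from an empty Pareto front")
    members = front.members
    if policy == "balanced":
        return min(
            members,
            key=lambda m: (max(m.mse_pf, m.mse_ecm), m.mse_pf, m.solution.params.k4),
        )
    if policy == "min_pf":
        return min(members, key=lambda m: (m.mse_pf, m.mse_ecm))
    if policy == "min_ecm":
        return min(members, key=lambda m: (m.mse_ecm, m.mse_pf))
    if policy != "knee":
        raise ValueError(f"unknown selection policy {policy!r}")
    pairs = front.objective_pairs()
    lo = pairs.min(axis=0)
    span = pairs.max(axis=0) - lo
    span[span == 0] = 1.0
    score = ((pairs - lo) / span).sum(axis=1)
    best = min(
        range(len(members)),
        key=lambda i: (score[i], members[i].mse_pf, members[i].solution.params.k4),
    )
    return members[best]


def fit(
    pf_data: ObservedDataset,
    ecm_data: ObservedDataset,
    n_iter: int,
    seed: int,
    ranges: Optional[SamplingRanges] = None,
    policy: str = "balanced",
    stability_tol: float = STABILITY_TOL,
    n_rounds: int = 10,
    elite_size: int = 20,
    explore_frac: float = 0.10,
    local_frac: float = 0.5,
    local_sd: float = 0.15,
) -> FitResult:
    """Run the stability-constrained iterative Monte Carlo Pareto fit.

    The ``n_iter`` draw budget is spread over ``n_rounds`` rounds.  Round
    one samples the full box; later rounds sample a box contracted around
    the current balanced elite (``elite_size`` best by Chebyshev score),
    spend ``local_frac`` of their budget on Gaussian perturbations of
    elite members, and keep ``explore_frac`` of draws on the full box.
    Candidates without a stable non-trivial fixed point are discarded
    before any objective is computed; the returned front is the
    non-dominated set over every accepted candidate of every round, and
    ``policy`` picks the reported solution.  Identical (seed, n_iter,
    ranges, data) reproduce identical results.  ``n_rounds=1`` gives plain
    uniform Monte Carlo sampling.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if ranges is None:
        ranges = default_ranges()
    n_rounds = min(n_rounds, n_iter)
    rng = np.random.default_rng(seed)
    lo0, hi0, is_log = ranges.arrays()
    eps = 1e-300

    def to_x(vals):  # working coordinates: log for log-scaled parameters
        return np.where(is_log, np.log(np.maximum(vals, eps)), vals)

    glo, ghi = to_x(lo0), to_x(hi0)
    lo_x, hi_x = glo.copy(), ghi.copy()

    n_per = n_iter // n_rounds
    budgets = [n_per + (n_iter - n_per * n_rounds)] + [n_per] * (n_rounds - 1)

    n_stable_total = 0
    n_failed_total = 0
    all_rows: list[np.ndarray] = []
    all_pairs: list[np.ndarray] = []
    elite: Optional[np.ndarray] = None
    with np.errstate(divide="ignore"):
        for rnd, budget in enumerate(budgets):
            if budget == 0:
                continue
            u = rng.random((budget, 9))
            explore = rng.random(budget) < (explore_frac if rnd else 1.0)
            a = np.where(explore[:, None], glo, lo_x)
            b = np.where(explore[:, None], ghi, hi_x)
            x = b - u * (b - a)  # in (a, b]: keeps linear draws > lower bound
            if elite is not None and local_frac > 0:
                nloc = int(budget * local_frac)
                if nloc:
                    centers = to_x(elite[rng.integers(0, elite.shape[0], nloc)])
                    width = hi_x - lo_x
                    sd_r = local_sd * (0.85**rnd)
                    xl = centers + rng.normal(0.0, 1.0, (nloc, 9)) * sd_r * width
                    xl = np.clip(xl, glo, ghi)
                    keep = ~explore[:nloc]
                    x[:nloc][keep] = xl[keep]
            vals = np.where(is_log, np.exp(x), x)
            # linear lower bounds are open (initial amounts stay positive)
            span = hi0 - lo0
            floor = lo0 + np.where(is_log, 0.0, 1e-9 * np.maximum(span, 1.0))
            vals = np.maximum(vals, np.minimum(floor, hi0))

            stable_mask = _batch_stable(vals[:, :7], stability_tol)
            n_stable_total += int(stable_mask.sum())
            sv = vals[stable_mask]
            if sv.shape[0] == 0:
                continue
            y0 = np.zeros((sv.shape[0], 3))
            y0[:, 0] = sv[:, 7]
            y0[:, 1] = sv[:, 8]
            mp, me, ok = _batch_objectives(sv, y0, pf_data, ecm_data, t0=10.5)
            n_failed_total += int((~ok).sum())
            if not np.any(ok):
                continue
            all_rows.append(sv[ok])
            all_pairs.append(np.stack([mp[ok], me[ok]], axis=1))
            rows = np.concatenate(all_rows)
            pairs = np.concatenate(all_pairs)
            cheb = np.maximum(pairs[:, 0], pairs[:, 1])
            elite = rows[np.argsort(cheb)[: min(elite_size, cheb.size)]]
            # contract the box around the elite, annealing the margin
            mfac = 0.3 * (0.8**rnd) + 0.05
            ex = to_x(elite)
            emin, emax = ex.min(axis=0), ex.max(axis=0)
            base_m = np.where(is_log, 0.05, 0.01 * np.maximum(span, 1.0))
            margin = mfac * (emax - emin) + base_m
            lo_x = np.maximum(glo, emin - margin)
            hi_x = np.minimum(ghi, emax + margin)

    if not all_pairs:
        front = ParetoFront((), n_iter, n_stable_total, seed, n_failed_total)
        return FitResult(front=front, selected=None)
    rows = np.concatenate(all_rows)
    pairs = np.concatenate(all_pairs)
    idx = pareto_front([tuple(p) for p in pairs])
    members = []
    seen = set()
    for i in idx:
        key = (pairs[i, 0], pairs[i, 1], tuple(rows[i]))
        if key in seen:
            continue
        seen.add(key)
        members.append(
            ParetoCandidate(
                solution=_to_solution(rows[i]),
                mse_pf=float(pairs[i, 0]),
                mse_ecm=float(pairs[i, 1]),
                stable=True,
            )
        )
    front = ParetoFront(tuple(members), n_iter, n_stable_total, seed, n_failed_total)
    selected = select_solution(front, policy=policy)
    return FitResult(front=front, selected=selected)


def _batch_stable(theta: np.ndarray, tol: float) -> np.ndarray:
    """Vectorised existence + stability filter for rows of rate constants."""
    b, k2, km2, k3, k4, k6, k7 = (theta[:, j] for j in range(7))
    with np.errstate(all="ignore"):
        num = km2 * (b + k2) + b * k6
        exists = (k4 > 0) & (k3 > 0) & (k6 > 0) & ((b + k2) > 0) & (num > 0)
        pf_star = np.where(exists, k7 * num / (k3 * k4 * (b + k2)), 0.0)
        ecm_star = np.where(exists, num / (k4 * k6), 0.0)
        n = theta.shape[0]
        J = np.zeros((n, 3, 3))
        J[:, 0, 0] = b - k4 * ecm_star
        J[:, 0, 1] = km2
        J[:, 0, 2] = -k4 * pf_star
        J[:, 1, 0] = k2 + k4 * ecm_star
        J[:, 1, 1] = -km2 - k6
        J[:, 1, 2] = k4 * pf_star
        J[:, 2, 1] = k3
        J[:, 2, 2] = -k7
        eig = np.linalg.eigvals(J)
        stable = np.max(eig.real, axis=1) < -tol
    return exists & stable
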