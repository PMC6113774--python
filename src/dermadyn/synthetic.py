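"""Synthetic observation datasets with the statistical structure of the
measured time courses.

Means come from the maturation ODE (or the wound PDE); per-time-point
Gaussian noise emulates the standard-deviation columns of the measured
tables.  Values are truncated to the [0, 100] percent range after noise is
added; the recorded sd column is always the generating sd, so downstream
fitting sees the same schema as the real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datasets import FitSolution, KineticParameters, ObservedDataset, ecm_observations, pf_observations
from .maturation import simulate
from .pareto import SamplingRanges, fit as pareto_fit_run
from .wound import WoundSpec, apply_wound, integrate, steady_field, wound_means

__all__ = ["NoiseModel", "synth_maturation", "synth_wound", "recovery_experiment"]


@dataclass(frozen=True)
class NoiseModel:
    """Per-time-point Gaussian noise specification.

    ``mode``: ``fixed_sd`` (one sd everywhere), ``table_sd`` (sds taken
    from the measured tables where times coincide, else ``sd`` as
    fallback), or ``proportional`` (sd = coefficient x mean).
    """

    mode: str = "table_sd"
    sd: float = 0.0
    coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_sd", "table_sd", "proportional"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sd < 0 or self.coefficient < 0:
            raise ValueError("sd and coefficient must be non-negative")

    def sds_for(self, observable: str, times: np.ndarray, means: np.ndarray) -> np.ndarray:
        if self.mode == "fixed_sd":
            return np.full(times.size, self.sd)
        if self.mode == "proportional":
            return self.coefficient * np.abs(means)
        table = pf_observations() if observable == "pf_percent" else ecm_observations()
        lookup = {t: s for t, _, s in table.records}
        return np.array([lookup.get(t, self.sd) for t in times])


def _noisy_dataset(
    name: str,
    times: np.ndarray,
    means: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> ObservedDataset:
    sds = noise.sds_for(name, times, means)
    values = means + rng.normal(0.0, 1.0, times.size) * sds
    values = np.clip(values, 0.0, 100.0)
    return ObservedDataset(name, tuple(zip(times, values, sds)))


def synth_maturation(
    solution: FitSolution,
    times_pf: Optional[Sequence[float]] = None,
    times_ecm: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(mode="fixed_sd", sd=0.0),
) -> tuple[ObservedDataset, ObservedDataset]:
    """Noisy PF% and ECM% time courses generated from the maturation model.

    Defaults to the measured tables' time grids, so synthetic and real
    datasets are drop-in interchangeable for the fitting machinery.
    """
    times_pf = np.asarray(times_pf if times_pf is not None else pf_observations().times, dtype=float)
    times_ecm = np.asarray(times_ecm if times_ecm is not None else ecm_observations().times, dtype=float)
    rng = np.random.default_rng(noise.seed)
    all_times = np.union1d(times_pf, times_ecm)
    if all_times[0] > solution.t0:
        all_times = np.concatenate([[solution.t0], all_times])
    traj = simulate(solution, all_times)
    idx = {t: i for i, t in enumerate(traj.times)}
    pf_means = traj.pf_percent()[[idx[t] for t in times_pf]]
    ecm_means = traj.ecm[[idx[t] for t in times_ecm]]
    pf_ds = _noisy_dataset("pf_percent", times_pf, pf_means, noise, rng)
    ecm_ds = _noisy_dataset("ecm_percent", times_ecm, np.clip(ecm_means, 0, 100), noise, rng)
    return pf_ds, ecm_ds


def synth_wound(
    params: KineticParameters,
    D: float,
    wound: WoundSpec = WoundSpec(),
    times: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(mode="fixed_sd", sd=0.0),
    n: int = 201,
    dt_out: float = 0.05,
) -> ObservedDataset:
    """Noisy wound-averaged PF% series from the reaction-diffusion model."""
    t_grid = np.asarray(times if times is not None else np.arange(0.0, 30.0 + 1e-9, 0.5))
    rng = np.random.default_rng(noise.seed)
    field = apply_wound(steady_field(params, n=n, D=D), wound)
    hist = integrate(field, params, t_end=float(t_grid[-1]), dt_out=dt_out)
    summary = wound_means(hist, wound)
    means = np.interp(t_grid, summary.times, summary.pf_bar_percent)
    # the series starts at an empty wound; shift t=0 slightly if duplicated
    return _noisy_dataset("pf_percent", t_grid, means, noise, rng)


def recovery_experiment(
    seed: int,
    n_iter: int,
    ranges: Optional[SamplingRanges] = None,
    truth: Optional[FitSolution] = None,
) -> dict:
    """Fit noiseless synthetic data and measure trajectory recovery.

    Generates noiseless PF% and ECM% series from ``truth`` (the published
    fit by default) on the measured time grids, runs the Monte Carlo
    Pareto fit, and reports the RMS deviation between the selected
    solution's curves and the generating curves on a dense grid over the
    observation window.  Parameter-level recovery is deliberately not
    scored: distinct parameter vectors can produce near-identical curves.
    """
    from .datasets import published_fit

    if truth is None:
        truth = published_fit()
    pf_ds, ecm_ds = synth_maturation(truth)
    result = pareto_fit_run(pf_ds, ecm_ds, n_iter=n_iter, seed=seed, ranges=ranges)
    report = {
        "seed": seed,
        "n_iter": n_iter,
        "n_stable": result.front.n_stable,
        "n_front": len(result.front.members),
    }
    if result.selected is None:
        report["selected"] = None
        return report
    sel = result.selected
    dense = np.linspace(10.5, 73.5, 127)
    t_true = simulate(truth, dense)
    t_fit = simulate(sel.solution, dense)
    report["selected"] = {
        "params": dict(zip(("beta", "k2", "km2", "k3", "k4", "k6", "k7"), sel.solution.params.as_tuple())),
        "pf0": sel.solution.pf0,
        "qf0": sel.solution.qf0,
        "mse_pf": sel.mse_pf,
        "mse_ecm": sel.mse_ecm,
    }
    report["rms_pf_percent"] = float(np.sqrt(np.mean((t_true.pf_percent() - t_fit.pf_percent()) ** 2)))
    report["rms_ecm"] = float(np.sqrt(np.mean((t_true.ecm - t_fit.ecm) ** 2)))
    return report
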