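"""Measured time courses of dermal maturation and the published model fit.

The package ships two experimental time series quantified in developing mouse
back skin: the fraction of fibroblasts that are proliferating (Ki67-positive,
as a percentage of all fibroblasts) and the total collagen content of the
dermis (percent Picrosirius-red-positive area), both indexed by days
post-conception (10.5 = E10.5, 19.5 is approximately birth).  It also ships
the published kinetic parameters and initial conditions of the
fibroblast/ECM negative-feedback model that fit those series.

Times are stored as printed, in days post-conception; no epoch conversion is
applied and values are kept at printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "ObservedDataset",
    "FitSolution",
    "pf_observations",
    "ecm_observations",
    "published_fit",
    "read_timeseries",
    "write_timeseries",
    "TimeseriesParseError",
]


class TimeseriesParseError(ValueError):
    """Raised when a time-series CSV cannot be parsed into an ObservedDataset."""


@dataclass(frozen=True)
class ObservedDataset:
    """One observable's measured time course: (time, value, sd) records.

    ``observable_name`` is ``"pf_percent"`` (proliferating fibroblasts as a
    percentage of all fibroblasts) or ``"ecm_percent"`` (percent collagen
    area).  Times must be strictly increasing, values within [0, 100] and
    standard deviations non-negative.
    """

    observable_name: str
    records: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        recs = tuple((float(t), float(v), float(s)) for t, v, s in self.records)
        object.__setattr__(self, "records", recs)
        times = [r[0] for r in recs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        for t, v, s in recs:
            if t < 0:
                raise ValueError(f"negative time {t}")
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"value {v} outside [0, 100]")
            if s < 0:
                raise ValueError(f"negative sd {s}")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(r[1] for r in self.records)

    @property
    def sds(self) -> tuple[float, ...]:
        return tuple(r[2] for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the fibroblast/ECM negative-feedback model.

    ``beta`` is the net proliferation rate of proliferating fibroblasts (it
    absorbs growth-factor-driven division, the basal entry into quiescence
    and basal loss, and may take either sign).  ``k2``/``km2`` are the
    forward/backward PF<->QF switching rates, ``k3`` the ECM deposition rate
    by quiescent fibroblasts, ``k4`` the strength of the catalytic
    ECM-driven entry into quiescence (the negative feedback), ``k6`` the
    quiescent-cell loss rate and ``k7`` the ECM turnover rate.  All rates
    are per day; ``k4`` is per (ECM unit x day).
    """

    beta: float
    k2: float
    km2: float
    k3: float
    k4: float
    k6: float
    k7: float

    def __post_init__(self) -> None:
        for name in ("k2", "km2", "k3", "k4", "k6", "k7"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.beta, self.k2, self.km2, self.k3, self.k4, self.k6, self.k7)


@dataclass(frozen=True)
class FitSolution:
    """A full model parameterisation: rate constants plus initial conditions.

    The initial state is given at ``t0`` days post-conception (the first
    measurement, E10.5 by default); the ECM amount starts at zero because no
    collagen is detectable at that stage.
    """

    params: KineticParameters
    pf0: float
    qf0: float
    ecm0: float = 0.0
    t0: float = 10.5

    def __post_init__(self) -> None:
        if self.pf0 < 0 or self.qf0 < 0:
            raise ValueError("initial amounts must be non-negative")
        if self.pf0 + self.qf0 <= 0:
            raise ValueError("pf0 + qf0 must be positive")
        if self.ecm0 != 0.0:
            raise ValueError("ecm0 is fixed at 0")


# The printed tables, kept verbatim as the in-code source of truth; the
# packaged CSV fixtures under data/ mirror these values exactly.
_PF_TABLE: tuple[tuple[float, float, float], ...] = (
    (10.5, 75.1, 1.4),
    (16.5, 46.5, 6.4),
    (17.5, 52.8, 2.8),
    (18.5, 51.0, 2.0),
    (19.5, 30.8, 4.8),
    (21.5, 13.5, 1.6),
    (29.5, 2.3, 1.4),
    (41.5, 1.5, 0.4),
    (59.5, 0.69, 0.1),
    (69.5, 0.44, 0.04),
)

_ECM_TABLE: tuple[tuple[float, float, float], ...] = (
    (10.5, 0.0, 0.0),
    (16.5, 0.3, 0.2),
    (17.5, 0.4, 0.4),
    (18.5, 12.1, 1.4),
    (19.5, 7.9, 0.8),
    (21.5, 17.4, 1.9),
    (24.5, 37.8, 1.1),
    (29.5, 45.4, 2.4),
    (31.5, 46.5, 3.3),
    (33.5, 57.2, 4.5),
    (35.5, 60.4, 3.9),
    (38.5, 64.7, 4.3),
    (40.5, 72.0, 5.6),
    (73.5, 88.3, 5.1),
)

_PUBLISHED = dict(
    beta=0.3010, k2=1.0102, km2=0.6084, k3=0.0610, k4=0.2008, k6=0.0424, k7=0.8380
)
_PUBLISHED_PF0 = 0.3530
_PUBLISHED_QF0 = 0.1166


def pf_observations() -> ObservedDataset:
    """The measured proliferating-fibroblast percentage over development."""
    return ObservedDataset("pf_percent", _PF_TABLE)


def ecm_observations() -> ObservedDataset:
    """The measured collagen (ECM) percentage over development."""
    return ObservedDataset("ecm_percent", _ECM_TABLE)


def published_fit() -> FitSolution:
    """The published Pareto-front parameterisation fitting both time courses."""
    return FitSolution(
        params=KineticParameters(**_PUBLISHED),
        pf0=_PUBLISHED_PF0,
        qf0=_PUBLISHED_QF0,
    )


_HEADER = ("time_days", "value_percent", "sd_percent")


def write_timeseries(dataset: ObservedDataset, path: Union[str, Path]) -> None:
    """Write a dataset as comma-separated text with a header row.

    Floats are written with `repr` so the round trip through
    :func:`read_timeseries` is lossless at full double precision.
    """
    path = Path(path)
    lines = [",".join(_HEADER)]
    for t, v, s in dataset.records:
        lines.append(f"{t!r},{v!r},{s!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_timeseries(
    path: Union[str, Path], observable_name: str = "pf_percent"
) -> ObservedDataset:
    """Parse a (time_days, value_percent, sd_percent) CSV into a dataset.

    Raises :class:`TimeseriesParseError` naming the offending line for
    missing, short or non-numeric rows, and for an empty file.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TimeseriesParseError(f"{path}: empty file")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise TimeseriesParseError(f"{path}: line {i}: expected 3 columns")
        try:
            t, v, s = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise TimeseriesParseError(f"{path}: line {i}: non-numeric value") from exc
        records.append((t, v, s))
    if not records:
        raise TimeseriesParseError(f"{path}: no data rows")
    try:
        return ObservedDataset(observable_name, tuple(records))
    except ValueError as exc:
        raise TimeseriesParseError(f"{path}: {exc}") from exc


def packaged_fixture_path(name: str) -> Path:
    """Path to a CSV fixture shipped inside the package (``table1_pf`` etc.)."""
    ref = resources.files("dermadyn") / "data" / f"{name}.csv"
    return Path(str(ref))
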