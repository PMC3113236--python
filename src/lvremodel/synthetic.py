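"""Synthetic validation-style observation series.

Real validation data for this model are fold-change time courses of
macrophage density, fibroblast density and MMP-9 concentration at a handful
of post-MI days, reported as mean +/- SD over a few animals and normalised
to the healthy LV.  This module emulates that structure from a simulated
trajectory: multiplicative log-normal noise (positive, right-skewed, as
fold-change data are) around the model's normalised value, with a
configurable coefficient of variation and replicate count, fully seeded.

The generator defines the package's study conditions for parameter
recovery: by default, the median-stimulus scenario sampled at days
{0, 1, 3, 5, 7, 14, 21, 28} — a typical post-MI harvest schedule — with
CV 10% and n = 5 replicates per day.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StimulusProfile
from .curves import InteractionCurveSet
from .params import ModelParameters
from .simulation import (
    ScenarioSpec,
    SolverSettings,
    Trajectory,
    normalize_to_baseline,
    simulate,
)

__all__ = [
    "NoiseModel",
    "ObservationSeries",
    "DEFAULT_SAMPLING_DAYS",
    "COMPONENT_MAP",
    "sample_observations",
    "make_validation_dataset",
    "observations_to_frame",
    "write_observations",
    "read_observations",
]

#: default post-MI harvest schedule, days
DEFAULT_SAMPLING_DAYS = (0.0, 1.0, 3.0, 5.0, 7.0, 14.0, 21.0, 28.0)

#: observable name -> trajectory component
COMPONENT_MAP = {"macrophage": "M_phi", "fibroblast": "F", "MMP-9": "M9A"}


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Replicate noise around the model's fold-change value.

    ``lognormal-multiplicative`` (default) draws value * exp(N(-s^2/2, s))
    with s chosen so the multiplicative CV equals ``cv`` (the mean is then
    exactly the model value); ``normal-additive`` draws value + N(0, cv*value).
    """

    cv: float = 0.1
    n: int = 5
    seed: int = 0
    distribution: str = "lognormal-multiplicative"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n < 1:
            raise ValueError("need at least one replicate")
        if self.distribution not in ("lognormal-multiplicative", "normal-additive"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def draw(self, value: float, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.full(self.n, value)
        if self.distribution == "lognormal-multiplicative":
            s = np.sqrt(np.log1p(self.cv**2))
            return value * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=self.n)
        return value + rng.normal(0.0, self.cv * abs(value), size=self.n)


@dataclasses.dataclass(frozen=True)
class ObservationSeries:
    """Mean +/- SD fold changes of one observable at a set of days."""

    component: str  # "macrophage" | "fibroblast" | "MMP-9"
    days: tuple[float, ...]
    mean_fold: tuple[float, ...]
    sd_fold: tuple[float, ...]
    n: tuple[int, ...]
    provenance: dict = dataclasses.field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.component not in COMPONENT_MAP:
            raise ValueError(f"unknown component {self.component!r}")
        days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(days < 0) or np.any(days > 30):
            raise ValueError("days must lie within [0, 30]")
        if np.any(np.asarray(self.mean_fold) <= 0):
            raise ValueError("mean fold changes must be > 0")
        if np.any(np.asarray(self.sd_fold) < 0):
            raise ValueError("SDs must be >= 0")
        if not (len(self.days) == len(self.mean_fold) == len(self.sd_fold) == len(self.n)):
            raise ValueError("ragged observation series")


def _digest(trajectory: Trajectory) -> str:
    h = hashlib.sha256()
    h.update(trajectory.t.tobytes())
    h.update(trajectory.y.tobytes())
    return h.hexdigest()[:16]


def sample_observations(
    trajectory: Trajectory,
    component: str,
    days=DEFAULT_SAMPLING_DAYS,
    noise: NoiseModel = NoiseModel(),
) -> ObservationSeries:
    """Draw a noisy mean +/- SD fold-change series from a trajectory.

    The trajectory is normalised to its t=0 state; at each requested day,
    ``noise.n`` replicates are drawn around the interpolated model fold
    change and summarised.  Reproducible for a fixed noise seed.
    """
    if component not in COMPONENT_MAP:
        raise KeyError(f"unknown component {component!r}; choose from {sorted(COMPONENT_MAP)}")
    days = np.asarray(days, dtype=float)
    if days.min() < trajectory.t[0] or days.max() > trajectory.t[-1]:
        raise ValueError("sampling days outside the trajectory span")
    fold = normalize_to_baseline(trajectory).component(COMPONENT_MAP[component])
    model_values = np.interp(days, trajectory.t, fold)

    rng = np.random.default_rng(noise.seed)
    means, sds = [], []
    for value in model_values:
        reps = noise.draw(float(value), rng)
        means.append(float(np.mean(reps)))
        # noise-free or single-replicate draws have no spread by construction
        if noise.cv == 0 or noise.n == 1:
            sds.append(0.0)
        else:
            sds.append(float(np.std(reps, ddof=1)))
    return ObservationSeries(
        component=component,
        days=tuple(days.tolist()),
        mean_fold=tuple(means),
        sd_fold=tuple(sds),
        n=(noise.n,) * days.size,
        provenance={
            "source_trajectory": _digest(trajectory),
            "noise": dataclasses.asdict(noise),
        },
    )


def make_validation_dataset(
    params: ModelParameters,
    curves: InteractionCurveSet,
    noise: NoiseModel = NoiseModel(),
    days=DEFAULT_SAMPLING_DAYS,
    solver: SolverSettings = SolverSettings(),
    stimulus: StimulusProfile | None = None,
) -> list[ObservationSeries]:
    """Three observation series (macrophage, fibroblast, MMP-9).

    Runs the median-stimulus scenario (amplitude 30 pg/uL/day peaking at
    day 2) and samples the three observables at the harvest days.  Distinct
    sub-seeds are derived for the three series so their noise is independent.
    """
    stimulus = stimulus or StimulusProfile(amplitude=30.0, peak_day=2.0)
    traj = simulate(ScenarioSpec("validation", stimulus), params, curves, solver=solver)
    series = []
    for k, component in enumerate(COMPONENT_MAP):
        sub = dataclasses.replace(noise, seed=int(noise.seed) * 3 + k)
        series.append(sample_observations(traj, component, days, sub))
    return series


# -- CSV interchange (shared schema with the calibration module) -------------

def observations_to_frame(series: list[ObservationSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for day, mean, sd, n in zip(s.days, s.mean_fold, s.sd_fold, s.n):
            rows.append({"day": day, "component": s.component,
                         "mean_fold": mean, "sd_fold": sd, "n": n})
    return pd.DataFrame(rows)


def write_observations(series: list[ObservationSeries], path: str | Path) -> None:
    """Write the shared observation CSV plus a JSON provenance sidecar."""
    path = Path(path)
    observations_to_frame(series).to_csv(path, index=False, float_format="%.17g")
    # (read back with float_precision="round_trip" for bit-exact recovery)
    sidecar = {s.component: s.provenance for s in series}
    path.with_suffix(".provenance.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_observations(path: str | Path) -> list[ObservationSeries]:
    frame = pd.read_csv(path, float_precision="round_trip")
    series = []
    for component, group in frame.groupby("component", sort=False):
        group = group.sort_values("day")
        series.append(ObservationSeries(
            component=str(component),
            days=tuple(group["day"].tolist()),
            mean_fold=tuple(group["mean_fold"].tolist()),
            sd_fold=tuple(group["sd_fold"].tolist()),
            n=tuple(int(v) for v in group["n"]),
            provenance={"source": str(path)},
        ))
    return series
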