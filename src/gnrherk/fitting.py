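"""Genetic-algorithm estimation of the fitted parameter subset.

The fitter mirrors the published procedure: a population of candidate
parameter vectors is initialized from a starting parameter set; each
generation every fitted parameter of every vector is perturbed
multiplicatively, theta_new = theta_current * (1 + 0.1*eps) with eps drawn
from a standard normal; goodness of fit is the weighted mean squared error
between model observables and the objective records; and the next population
is drawn with replacement with probability proportional to fitness rank
(best vector -> largest rank weight).  One elite — the best vector found so
far — is carried through each generation unmutated, which makes the
best-so-far fitness non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import FITTED_PARAMS, ParameterSet
from .protocols import PulseProtocol

__all__ = ["OBSERVABLE_KINDS", "ObjectiveSet", "FitResult", "mutate", "fitness", "select", "fit"]

OBSERVABLE_KINDS = ("nc_erk", "nc_erk_norm", "pperk_wholecell", "tf1dt")

_RECORD_COLUMNS = ["protocol_id", "observable", "time_min", "value", "weight"]


class ObjectiveSet:
    """Weighted pseudo-observations tying protocols to target observable values.

    Parameters
    ----------
    protocols : mapping of protocol id -> :class:`PulseProtocol`.
    records : DataFrame with columns (protocol_id, observable, time_min,
        value, weight).  ``observable`` is one of ``nc_erk`` (raw N:C ratio),
        ``nc_erk_norm`` (N:C normalized to its resting value),
        ``pperk_wholecell`` (uM) or ``tf1dt`` (uM, e.g. an endpoint reporter
        proxy); ``time_min`` must lie within the protocol horizon and weights
        must be positive.
    """

    def __init__(self, protocols: Mapping[str, PulseProtocol], records: pd.DataFrame):
        records = pd.DataFrame(records)[_RECORD_COLUMNS].reset_index(drop=True)
        unknown = set(records["protocol_id"]) - set(protocols)
        if unknown:
            raise ValueError(f"records reference unknown protocol ids: {sorted(unknown)}")
        bad_obs = set(records["observable"]) - set(OBSERVABLE_KINDS)
        if bad_obs:
            raise ValueError(f"unknown observables: {sorted(bad_obs)}")
        if (records["weight"] <= 0).any():
            raise ValueError("weights must be > 0")
        for pid, group in records.groupby("protocol_id"):
            horizon = protocols[pid].horizon
            if (group["time_min"] < 0).any() or (group["time_min"] > horizon).any():
                raise ValueError(f"objective times outside [0, {horizon}] for {pid!r}")
        self.protocols = dict(protocols)
        self.records = records
        self._plans: dict[str, tuple] = {}
        # per-protocol record views, precomputed once for the fitness loop
        self._groups: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = [
            (
                pid,
                group.index.to_numpy(),
                group["time_min"].to_numpy(dtype=float),
                group["observable"].to_numpy(),
            )
            for pid, group in records.groupby("protocol_id")
        ]
        self._values = records["value"].to_numpy(dtype=float)
        self._weights = records["weight"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    def plan(self, pid: str):
        """Cached parameter-independent integration plan for one protocol."""
        if pid not in self._plans:
            from ._fast import protocol_plan

            times = self.records.loc[self.records["protocol_id"] == pid, "time_min"]
            self._plans[pid] = protocol_plan(self.protocols[pid], times.to_numpy())
        return self._plans[pid]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a genetic-algorithm fit."""

    best_params: ParameterSet
    best_fitness: float
    history: tuple[float, ...]  # best-so-far fitness per generation
    seed: int
    pop_size: int
    generations: int

    def to_dict(self) -> dict:
        return {
            "best_parameters": self.best_params.to_dict(),
            "best_fitness": self.best_fitness,
            "history": list(self.history),
            "seed": self.seed,
            "pop_size": self.pop_size,
            "generations": self.generations,
        }


def mutate(
    params: ParameterSet, scale: float = 0.1, rng: np.random.Generator | None = None
) -> ParameterSet:
    """Multiplicatively perturb the fitted parameter subset.

    Each flagged parameter is multiplied by (1 + scale*eps), eps i.i.d.
    standard normal, floored at 1e-12 to preserve positivity; all other
    parameters are untouched.
    """
    if rng is None:
        rng = np.random.default_rng()
    values = params.fitted_values()
    eps = rng.standard_normal(len(values))
    new = np.maximum(values * (1.0 + scale * eps), 1e-12)
    return params.with_fitted_values(new)


def _model_values(
    params: ParameterSet, objectives: ObjectiveSet, integrator: str, dt: float
) -> np.ndarray:
    """Model predictions for every objective record, in record order."""
    rest_nc = params.C_cn * params.k_imp / params.k_exp
    C = params.C_cn
    out = np.empty(len(objectives.records))
    for pid, rec_idx, times_wanted, obs in objectives._groups:
        if integrator == "fast":
            from ._fast import fast_states

            times, states = fast_states(
                params, objectives.protocols[pid], times_wanted, dt=dt,
                plan=objectives.plan(pid),
            )
        elif integrator == "reference":
            from .simulate import simulate

            traj = simulate(params, objectives.protocols[pid], output_step=dt)
            times = np.unique(times_wanted)
            # interpolate each state component onto the requested times
            states = np.column_stack(
                [np.interp(times, traj.t, traj.y[:, i]) for i in range(10)]
            )
        else:
            raise ValueError(f"unknown integrator {integrator!r}")
        idx = np.searchsorted(times, times_wanted)
        s = np.clip(states[idx], 0.0, None)
        cyt = s[:, 3] + s[:, 4] + s[:, 5]
        values = np.empty(len(times_wanted))
        with np.errstate(divide="ignore", invalid="ignore"):
            nc = (s[:, 6] + s[:, 7]) / cyt
        values[obs == "nc_erk"] = nc[obs == "nc_erk"]
        values[obs == "nc_erk_norm"] = nc[obs == "nc_erk_norm"] / rest_nc
        wc = (C * s[:, 5] + s[:, 7]) / (C + 1.0)
        values[obs == "pperk_wholecell"] = wc[obs == "pperk_wholecell"]
        values[obs == "tf1dt"] = s[:, 9][obs == "tf1dt"]
        out[rec_idx] = values
    return out


def fitness(
    params: ParameterSet,
    objectives: ObjectiveSet,
    integrator: str = "fast",
    dt: float = 0.02,
) -> float:
    """Weighted mean squared error of the model against the objectives.

    Returns +inf (culling the candidate) if the model evaluation produces
    non-finite values.
    """
    try:
        model = _model_values(params, objectives, integrator, dt)
    except (ValueError, FloatingPointError, ZeroDivisionError, RuntimeError):
        return math.inf
    if not np.all(np.isfinite(model)):
        return math.inf
    w = objectives._weights
    resid = model - objectives._values
    return float(np.sum(w * resid**2) / np.sum(w))


def rank_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Selection probabilities proportional to fitness rank (best gets N).

    Ties keep their stable input order, so identical fitnesses receive
    adjacent ranks deterministically.
    """
    f = np.asarray(fitnesses, dtype=float)
    n = len(f)
    order = np.argsort(f, kind="stable")  # best (smallest MSE) first
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # best -> n, worst -> 1
    return ranks / ranks.sum()


def select(
    population: Sequence[ParameterSet],
    fitnesses: Sequence[float],
    rng: np.random.Generator,
) -> list[ParameterSet]:
    """Rank-proportional sampling with replacement to the same population size."""
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    if len(population) == 1:
        return list(population)
    probs = rank_probabilities(fitnesses)
    idx = rng.choice(len(population), size=len(population), replace=True, p=probs)
    return [population[i] for i in idx]


def fit(
    objectives: ObjectiveSet,
    init: ParameterSet,
    generations: int = 150,
    pop_size: int = 50,
    seed: int = 0,
    mutation_scale: float = 0.1,
    integrator: str = "fast",
    dt: float = 0.02,
) -> FitResult:
    """Run the genetic algorithm and return the best-ever parameter vector.

    The population starts as ``pop_size`` copies of ``init``; each generation
    mutates every vector (one elite slot excepted), evaluates fitness, and
    rank-selects the next population.  Fully reproducible from ``seed``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = np.random.default_rng(seed)
    population = [init] * pop_size
    best_params = init
    best_fitness = fitness(init, objectives, integrator=integrator, dt=dt)
    history: list[float] = []
    for _ in range(generations):
        candidates = [mutate(v, mutation_scale, rng) for v in population]
        candidates[0] = best_params  # elite passes through unmutated
        fits = np.empty(pop_size)
        fits[0] = best_fitness
        for i in range(1, pop_size):
            fits[i] = fitness(candidates[i], objectives, integrator=integrator, dt=dt)
        if not np.any(np.isfinite(fits)):
            raise RuntimeError("all candidates failed evaluation (non-finite fitness)")
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fitness:
            best_fitness = float(fits[gen_best])
            best_params = candidates[gen_best]
        history.append(best_fitness)
        population = select(candidates, fits, rng)
    return FitResult(
        best_params=best_params,
        best_fitness=best_fitness,
        history=tuple(history),
        seed=seed,
        pop_size=pop_size,
        generations=generations,
    )
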