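"""Exact stochastic simulation of lineage dynamics.

Counts evolve as a continuous-time Markov jump process: process ``k``
fires with the clipped piecewise-linear intensity ``Q_k(counts)`` and
changes the counts by its increment vector. Two time semantics are
provided:

``"clock"``
    Standard exact SSA: exponential waiting times with the total
    intensity, process chosen with probability ``Q_k / sum_m Q_m``.
    This is the default, matching the continuous-time assumptions of the
    covariance theory.
``"discrete"``
    One event per unit "time" step with the same selection
    probabilities — a per-update scheme useful when only the embedded
    jump chain matters.

Process selection and waiting times consume two *separate* seeded
streams, so the two modes produce the identical event sequence for the
same seed; only the time stamps differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import LineageModel, SystemState

__all__ = ["TrajectorySet", "EmpiricalMoments", "EnsembleSummary",
           "NegativeCountError", "ssa_run", "scenario_run",
           "empirical_moments", "ensemble"]


class NegativeCountError(RuntimeError):
    """A selected process would drive a count negative (model inconsistency)."""


@dataclass(frozen=True)
class TrajectorySet:
    """A single seeded run: event times, counts, and event labels."""

    times: np.ndarray            # (T,), strictly increasing (clock) or 0..T-1
    counts: np.ndarray           # (T, n) nonnegative integers
    seed: int
    mode: str                    # "clock" | "discrete"
    event_indices: np.ndarray    # (T-1,) process index fired between rows
    process_names: tuple[str, ...]
    compartment_names: tuple[str, ...]
    absorbed: bool = False       # run hit an all-rates-zero state early

    @property
    def events(self) -> list[str]:
        return [self.process_names[k] for k in self.event_indices]

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class EmpiricalMoments:
    """Time-weighted moments of a post-burn-in trajectory segment."""

    means: np.ndarray
    covariances: np.ndarray
    se_means: np.ndarray         # batch-means standard errors
    n_effective: int             # events in the post-burn-in segment
    burn_in: float


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-replicate moments and recovery times plus pooled means."""

    replicate_means: np.ndarray       # (R, n)
    recovery_times: list[dict]        # per replicate: compartment -> time|None
    pooled_means: np.ndarray
    seeds: tuple[int, ...]
    horizon: float
    recovery_band: float
    trajectories: list[TrajectorySet] = field(repr=False, default_factory=list)


def ssa_run(model: LineageModel,
            init: SystemState | Sequence[int],
            horizon: float | None,
            seed: int,
            mode: str = "clock",
            max_events: int | None = None) -> TrajectorySet:
    """Simulate one trajectory.

    Parameters
    ----------
    init:
        Initial nonnegative counts (or a :class:`SystemState`).
    horizon:
        Stop once the clock passes this time (unit steps in discrete
        mode). May be None if ``max_events`` is given.
    max_events:
        Optional hard cap on the number of events.
    """
    if mode not in ("clock", "discrete"):
        raise ValueError(f"mode must be 'clock' or 'discrete', got {mode!r}")
    if horizon is None and max_events is None:
        raise ValueError("provide a horizon or max_events")
    if horizon is not None and horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    counts0 = np.asarray(init.counts if isinstance(init, SystemState) else init,
                         dtype=float)
    if counts0.shape != (model.n_compartments,):
        raise ValueError("init has wrong length")
    if (counts0 < 0).any():
        raise ValueError("init counts must be nonnegative")

    Q0 = model.equilibrium_rate_vector()
    C = model.control_matrix()
    D_cols = model.increment_matrix().astype(float).T  # (K, n)
    eq = np.asarray(model.equilibrium_populations, dtype=float)

    # Independent streams keep the embedded jump chain identical across modes.
    rng_sel = np.random.default_rng([seed, 0])
    rng_time = np.random.default_rng([seed, 1])

    t = 0.0
    counts = counts0.copy()
    times = [0.0]
    traj = [counts.copy()]
    fired: list[int] = []
    absorbed = False

    while True:
        if max_events is not None and len(fired) >= max_events:
            break
        rates = Q0 + C @ (counts - eq)
        np.maximum(rates, 0.0, out=rates)
        total = rates.sum()
        if total <= 0.0:
            absorbed = True
            break
        u = rng_sel.random() * total
        k = int(np.searchsorted(np.cumsum(rates), u))
        k = min(k, len(rates) - 1)  # guard against float round-off at the edge
        dt = rng_time.exponential(1.0 / total) if mode == "clock" else 1.0
        if horizon is not None and t + dt > horizon:
            break
        t += dt
        counts = counts + D_cols[k]
        if (counts < 0).any():
            raise NegativeCountError(
                f"process '{model.process_names[k]}' drove a count negative "
                f"at t={t:.6g}; the model's clipped rates are inconsistent")
        times.append(t)
        traj.append(counts.copy())
        fired.append(k)

    return TrajectorySet(times=np.array(times),
                         counts=np.array(traj, dtype=int),
                         seed=seed, mode=mode,
                         event_indices=np.array(fired, dtype=int),
                         process_names=model.process_names,
                         compartment_names=model.compartment_names,
                         absorbed=absorbed)


def scenario_run(model: LineageModel,
                 depletion: Mapping[str, float] | Sequence[float],
                 horizon: float | None,
                 seed: int,
                 mode: str = "clock",
                 max_events: int | None = None) -> TrajectorySet:
    """Run from a depleted/expanded initial state.

    ``depletion`` gives per-compartment multipliers of the equilibrium
    populations (mapping by name, or a full sequence); the initial counts
    are ``round(multiplier * i*)``. Multipliers of 1 reproduce a
    homeostatic run.
    """
    eq = np.asarray(model.equilibrium_populations, dtype=float)
    if isinstance(depletion, Mapping):
        mult = np.ones(model.n_compartments)
        for name, m in depletion.items():
            if name not in model.compartment_names:
                raise KeyError(f"unknown compartment '{name}'")
            mult[model.compartment_names.index(name)] = m
    else:
        mult = np.asarray(depletion, dtype=float)
        if mult.shape != eq.shape:
            raise ValueError("depletion multiplier length mismatch")
    if (mult < 0).any():
        raise ValueError("depletion multipliers must be >= 0")
    init = np.rint(mult * eq).astype(int)
    return ssa_run(model, init, horizon, seed, mode=mode, max_events=max_events)


def _segment(traj: TrajectorySet, burn_in: float):
    """Post-burn-in (times, counts, interval weights); last state dropped."""
    times, counts = traj.times, traj.counts.astype(float)
    t_end = times[-1]
    t0 = burn_in * t_end if 0.0 <= burn_in < 1.0 else float(burn_in)
    keep = times >= t0
    if keep.sum() < 2:
        raise ValueError("post-burn-in segment is empty or a single point")
    times, counts = times[keep], counts[keep]
    w = np.diff(times)           # holding time of each state but the last
    return times[:-1], counts[:-1], w


def empirical_moments(traj: TrajectorySet,
                      burn_in: float = 0.5,
                      n_batches: int = 20) -> EmpiricalMoments:
    """Time-weighted mean and covariance after burn-in.

    ``burn_in`` in [0, 1) is a fraction of the run duration; values >= 1
    are an absolute time. In discrete mode the unit holding times make
    this an event-weighted average. Standard errors of the means come
    from batch means over ``n_batches`` equal-duration batches.
    """
    t, c, w = _segment(traj, burn_in)
    W = w.sum()
    means = (w @ c) / W
    dev = c - means
    cov = (dev.T * w) @ dev / W

    edges = np.linspace(t[0], t[0] + W if traj.mode == "discrete" else traj.times[-1],
                        n_batches + 1)
    batch_means = []
    idx = np.searchsorted(edges, t, side="right") - 1
    idx = np.clip(idx, 0, n_batches - 1)
    for b in range(n_batches):
        sel = idx == b
        if w[sel].sum() > 0:
            batch_means.append((w[sel] @ c[sel]) / w[sel].sum())
    bm = np.array(batch_means)
    if len(bm) > 1:
        se = bm.std(axis=0, ddof=1) / np.sqrt(len(bm))
    else:
        se = np.full(c.shape[1], np.nan)
    return EmpiricalMoments(means=means, covariances=cov, se_means=se,
                            n_effective=len(t), burn_in=burn_in)


def _recovery_time(traj: TrajectorySet, comp_idx: int, eq_value: float,
                   band: float) -> float | None:
    """First passage into the +/- band*equilibrium window, or None."""
    inside = np.abs(traj.counts[:, comp_idx] - eq_value) <= band * eq_value
    hits = np.nonzero(inside)[0]
    return float(traj.times[hits[0]]) if hits.size else None


def ensemble(model: LineageModel,
             n_replicates: int,
             depletion: Mapping[str, float] | Sequence[float],
             horizon: float | None,
             seed: int,
             mode: str = "clock",
             burn_in: float = 0.5,
             recovery_band: float = 0.1,
             max_events: int | None = None,
             keep_trajectories: bool = False) -> EnsembleSummary:
    """Seeded independent replicates of a scenario with recovery times.

    Replicate ``r`` uses seed ``seed + r``. Recovery time of a perturbed
    compartment (multiplier != 1) is the first passage of its count into
    ``+/- recovery_band`` of its equilibrium value; ``None`` if the
    horizon is reached first.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    eq = np.asarray(model.equilibrium_populations, dtype=float)
    if isinstance(depletion, Mapping):
        mult = np.ones(model.n_compartments)
        for name, m in depletion.items():
            mult[model.compartment_names.index(name)] = m
    else:
        mult = np.asarray(depletion, dtype=float)
    perturbed = [i for i, m in enumerate(mult) if m != 1.0]

    rep_means, rec_times, trajs = [], [], []
    for r in range(n_replicates):
        traj = scenario_run(model, mult, horizon, seed + r, mode=mode,
                            max_events=max_events)
        rep_means.append(empirical_moments(traj, burn_in=burn_in).means)
        rec_times.append({
            model.compartment_names[i]:
                _recovery_time(traj, i, eq[i], recovery_band)
            for i in perturbed})
        if keep_trajectories:
            trajs.append(traj)
    rep_means = np.array(rep_means)
    return EnsembleSummary(replicate_means=rep_means,
                           recovery_times=rec_times,
                           pooled_means=rep_means.mean(axis=0),
                           seeds=tuple(seed + r for r in range(n_replicates)),
                           horizon=horizon if horizon is not None else float("nan"),
                           recovery_band=recovery_band,
                           trajectories=trajs)
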