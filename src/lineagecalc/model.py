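"""Core data structures for feedback-controlled cell-lineage models.

A lineage model is a list of cell compartments (cell types with equilibrium
population sizes) together with a list of cellular processes. Each process
— a division, differentiation, de-differentiation or death event — changes
the compartment counts by a fixed integer increment vector per occurrence,
and fires with a total intensity (events per unit time, *not* per cell)
that responds linearly to deviations of the populations from equilibrium:

    Q_k(i) = max(0,  Q_k0 + sum_q c_kq * (i_q - i*_q))

where ``Q_k0`` is the equilibrium intensity and ``c_kq`` is the "control"
— the signed partial derivative of the rate with respect to compartment
``q``, evaluated at equilibrium. A negative control is an inhibitory
feedback loop, a positive one an activating loop. The clipping at zero
makes the rate law piecewise linear; analyses that are local to the
equilibrium (Jacobian, covariances) use the unclipped linear form.

Compartment order is declaration order and fixes the index convention of
every vector and matrix produced by the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DERIVED",
    "ModelValidationError",
    "UnresolvedRatesError",
    "Process",
    "LineageModel",
    "SystemState",
    "build_model",
]

#: Sentinel used as a process ``rate`` to mark it for the equilibrium solver.
DERIVED = "derived"


class ModelValidationError(ValueError):
    """A model specification violates an invariant; message names the field."""


class UnresolvedRatesError(RuntimeError):
    """An operation needed numeric equilibrium rates but some are 'derived'."""


@dataclass(frozen=True)
class Process:
    """One cellular event type.

    Parameters
    ----------
    name:
        Label, unique within a model.
    increments:
        Integer population change per event, one entry per compartment.
    rate:
        Equilibrium intensity ``Q_k0`` in events per unit time (total,
        not per cell), or the string ``"derived"`` to have it determined
        by the equilibrium constraint solver.
    controls:
        Map compartment name -> dQ_k/di_q (events per unit time per cell).
    control_signs:
        Optional required sign per controlled compartment, ``"+"`` or
        ``"-"``; a numeric control violating its annotation is a
        validation error.
    """

    name: str
    increments: tuple[int, ...]
    rate: float | str = 0.0
    controls: Mapping[str, float] = field(default_factory=dict)
    control_signs: Mapping[str, str] = field(default_factory=dict)

    @property
    def is_derived(self) -> bool:
        return isinstance(self.rate, str)

    def with_rate(self, rate: float) -> "Process":
        return Process(self.name, self.increments, float(rate),
                       dict(self.controls), dict(self.control_signs))


@dataclass(frozen=True)
class SystemState:
    """Compartment counts at a time point (simulation-side state)."""

    counts: tuple[int, ...]
    time: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ModelValidationError(f"negative count in state {self.counts}")
        if self.time < 0:
            raise ModelValidationError("state time must be nonnegative")


@dataclass(frozen=True)
class LineageModel:
    """A validated multi-compartment lineage model.

    The single source of truth for every analysis in the package: the
    equilibrium populations, the process table (increments, equilibrium
    intensities) and the control derivatives.
    """

    compartment_names: tuple[str, ...]
    equilibrium_populations: tuple[float, ...]
    processes: tuple[Process, ...]

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        names = self.compartment_names
        if len(names) < 1:
            raise ModelValidationError("at least one compartment required")
        if len(set(names)) != len(names):
            raise ModelValidationError(f"duplicate compartment names in {names}")
        if len(self.equilibrium_populations) != len(names):
            raise ModelValidationError(
                "equilibrium_populations length "
                f"{len(self.equilibrium_populations)} != {len(names)} compartments")
        for nm, pop in zip(names, self.equilibrium_populations):
            if not pop > 0:
                raise ModelValidationError(
                    f"equilibrium population of '{nm}' must be positive, got {pop}")
        if len(self.processes) < 1:
            raise ModelValidationError("at least one process required")
        pnames = [p.name for p in self.processes]
        if len(set(pnames)) != len(pnames):
            raise ModelValidationError(f"duplicate process names in {pnames}")
        for p in self.processes:
            if len(p.increments) != len(names):
                raise ModelValidationError(
                    f"process '{p.name}': increment length {len(p.increments)} "
                    f"!= {len(names)} compartments")
            if not any(p.increments):
                raise ModelValidationError(
                    f"process '{p.name}': all-zero increment vector")
            if any(int(d) != d for d in p.increments):
                raise ModelValidationError(
                    f"process '{p.name}': increments must be integers")
            if not p.is_derived and p.rate < 0:
                raise ModelValidationError(
                    f"process '{p.name}': equilibrium rate must be >= 0, got {p.rate}")
            for comp in p.controls:
                if comp not in names:
                    raise ModelValidationError(
                        f"process '{p.name}': control references undeclared "
                        f"compartment '{comp}'")
            for comp, sign in p.control_signs.items():
                if comp not in names:
                    raise ModelValidationError(
                        f"process '{p.name}': sign annotation references "
                        f"undeclared compartment '{comp}'")
                if sign not in ("+", "-"):
                    raise ModelValidationError(
                        f"process '{p.name}': sign annotation must be '+' or '-', "
                        f"got {sign!r}")
                val = p.controls.get(comp, 0.0)
                if sign == "+" and val < 0 or sign == "-" and val > 0:
                    raise ModelValidationError(
                        f"process '{p.name}': control on '{comp}' is {val} "
                        f"but annotated '{sign}'")

    # -- basic shape ---------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_names)

    @property
    def n_processes(self) -> int:
        return len(self.processes)

    @property
    def process_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.processes)

    @property
    def derived_process_names(self) -> tuple[str, ...]:
        """Processes whose equilibrium rate awaits the constraint solver."""
        return tuple(p.name for p in self.processes if p.is_derived)

    def process_index(self, name: str) -> int:
        try:
            return self.process_names.index(name)
        except ValueError:
            raise KeyError(f"no process named '{name}'") from None

    # -- matrix views --------------------------------------------------

    def increment_matrix(self) -> np.ndarray:
        """n x K integer matrix; column k is the increment vector of process k."""
        return np.array([p.increments for p in self.processes], dtype=int).T

    def equilibrium_rate_vector(self) -> np.ndarray:
        """Vector (Q_10, ..., Q_K0); raises if any rate is still 'derived'."""
        unresolved = self.derived_process_names
        if unresolved:
            raise UnresolvedRatesError(
                f"equilibrium rates unresolved for {unresolved}; "
                "run the equilibrium solver first")
        return np.array([p.rate for p in self.processes], dtype=float)

    def control_matrix(self) -> np.ndarray:
        """K x n matrix of control derivatives dQ_k/di_q (zeros where absent)."""
        C = np.zeros((self.n_processes, self.n_compartments))
        for k, p in enumerate(self.processes):
            for comp, val in p.controls.items():
                C[k, self.compartment_names.index(comp)] = val
        return C

    # -- rate evaluation -----------------------------------------------

    def rates_at(self, counts: Sequence[float]) -> np.ndarray:
        """Clipped piecewise-linear process intensities at the given counts."""
        dev = np.asarray(counts, dtype=float) - np.asarray(self.equilibrium_populations)
        raw = self.equilibrium_rate_vector() + self.control_matrix() @ dev
        return np.maximum(raw, 0.0)

    def rate_at_state(self, k: int, state: SystemState | Sequence[float]) -> float:
        """Intensity of process ``k`` at a state; exactly Q_k0 at equilibrium."""
        if not 0 <= k < self.n_processes:
            raise IndexError(f"process index {k} out of range [0, {self.n_processes})")
        counts = state.counts if isinstance(state, SystemState) else state
        return float(self.rates_at(counts)[k])

    def drift(self, state: SystemState | Sequence[float]) -> np.ndarray:
        """Deterministic drift sum_k Q_k(state) * increments_k (clipped rates)."""
        counts = state.counts if isinstance(state, SystemState) else state
        return self.increment_matrix() @ self.rates_at(counts)

    # -- derived copies ------------------------------------------------

    def with_rates(self, rates: Mapping[str, float] | Sequence[float]) -> "LineageModel":
        """Return a copy with equilibrium rates replaced.

        ``rates`` is either a full-length sequence in process order or a
        name->value mapping (processes absent from the mapping keep their
        current rate).
        """
        if isinstance(rates, Mapping):
            new = [p.with_rate(rates[p.name]) if p.name in rates else p
                   for p in self.processes]
        else:
            if len(rates) != self.n_processes:
                raise ModelValidationError(
                    f"rate vector length {len(rates)} != {self.n_processes} processes")
            new = [p.with_rate(r) for p, r in zip(self.processes, rates)]
        return LineageModel(self.compartment_names,
                            self.equilibrium_populations, tuple(new))

    # -- (de)serialisation ---------------------------------------------

    def to_spec(self) -> dict[str, Any]:
        """Round-trippable plain-dict model specification."""
        return {
            "compartments": [
                {"name": n, "equilibrium": pop}
                for n, pop in zip(self.compartment_names, self.equilibrium_populations)
            ],
            "processes": [
                {
                    "name": p.name,
                    "increments": list(p.increments),
                    "rate": p.rate,
                    **({"controls": dict(p.controls)} if p.controls else {}),
                    **({"control_signs": dict(p.control_signs)}
                       if p.control_signs else {}),
                }
                for p in self.processes
            ],
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_spec(), indent=indent)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelValidationError(msg)


def build_model(spec: Mapping[str, Any]) -> LineageModel:
    """Build and validate a :class:`LineageModel` from a plain specification.

    The specification is a mapping with keys ``compartments`` (list of
    ``{"name", "equilibrium"}``) and ``processes`` (list of ``{"name",
    "increments", "rate", "controls", "control_signs"}``); ``rate`` may be
    a number or the string ``"derived"``. See ``LineageModel.to_spec`` for
    the inverse.
    """
    _require(isinstance(spec, Mapping), "model specification must be a mapping")
    for key in ("compartments", "processes"):
        _require(key in spec, f"model specification missing key '{key}'")
    comps = spec["compartments"]
    _require(isinstance(comps, Iterable) and not isinstance(comps, (str, bytes)),
             "'compartments' must be a list")
    names, pops = [], []
    for c in comps:
        _require(isinstance(c, Mapping) and "name" in c and "equilibrium" in c,
                 "each compartment needs 'name' and 'equilibrium'")
        names.append(str(c["name"]))
        pops.append(float(c["equilibrium"]))
    procs = []
    for p in spec["processes"]:
        _require(isinstance(p, Mapping) and "name" in p and "increments" in p,
                 "each process needs 'name' and 'increments'")
        rate = p.get("rate", 0.0)
        if isinstance(rate, str):
            _require(rate == DERIVED,
                     f"process '{p['name']}': rate must be a number or 'derived', "
                     f"got {rate!r}")
        else:
            rate = float(rate)
        procs.append(Process(
            name=str(p["name"]),
            increments=tuple(int(d) for d in p["increments"]),
            rate=rate,
            controls={str(k): float(v) for k, v in p.get("controls", {}).items()},
            control_signs={str(k): str(v)
                           for k, v in p.get("control_signs", {}).items()},
        ))
    return LineageModel(tuple(names), tuple(pops), tuple(procs))
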