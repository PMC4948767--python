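"""Equilibrium rate constraints.

At a homeostatic equilibrium the deterministic drift vanishes in every
compartment: the increment matrix ``D`` (n x K) applied to the vector of
equilibrium intensities ``Q0`` must satisfy ``D @ Q0 = 0``. Read as a
linear system in the unknown rates, this imposes ``rank(D)`` independent
constraints, so only ``K - rank(D)`` rates can be assigned freely; the
remaining ("dependent") rates follow linearly and must come out
nonnegative for the assignment to be feasible.

For generic models the free/dependent partition is chosen by pivoted QR
for conditioning; presets may pin a partition so that the derived
formulas match a published form symbol-for-symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .model import LineageModel

__all__ = ["ConstraintSystem", "RateSolution", "constraint_system",
           "constraint_rank", "solve_rates"]

#: Relative singular-value cutoff for rank decisions. Increments are small
#: integers, so the spectrum gap is enormous and this is safe.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class ConstraintSystem:
    """The equilibrium balance system ``D @ Q0 = 0`` in solved form.

    ``coefficients`` maps free rates to dependent ones:
    ``Q0[dependent] = coefficients @ Q0[free]`` (the system is homogeneous,
    so the map is linear with no offset).
    """

    matrix: np.ndarray                 # n x K increment matrix
    rank: int
    process_names: tuple[str, ...]
    free_indices: tuple[int, ...]
    dependent_indices: tuple[int, ...]
    coefficients: np.ndarray           # rank x n_free

    @property
    def n_free(self) -> int:
        return len(self.free_indices)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.process_names[i] for i in self.free_indices)

    @property
    def dependent_names(self) -> tuple[str, ...]:
        return tuple(self.process_names[i] for i in self.dependent_indices)

    def to_dict(self) -> dict:
        """JSON-ready report: rank, partition, and affine coefficients."""
        return {
            "rank": self.rank,
            "degrees_of_freedom": len(self.free_indices),
            "free": list(self.free_names),
            "dependent": [
                {"name": name,
                 "coefficients": {fn: float(c)
                                  for fn, c in zip(self.free_names, row)
                                  if c != 0.0}}
                for name, row in zip(self.dependent_names, self.coefficients)
            ],
        }


@dataclass(frozen=True)
class RateSolution:
    """Full equilibrium rate vector with a feasibility flag.

    ``feasible`` is False when some derived rate is negative; callers doing
    rejection sampling inspect the flag instead of catching exceptions.
    """

    rates: np.ndarray
    feasible: bool
    process_names: tuple[str, ...]

    def as_mapping(self) -> dict[str, float]:
        return {n: float(r) for n, r in zip(self.process_names, self.rates)}


def constraint_system(model: LineageModel,
                      dependent: Sequence[str] | None = None) -> ConstraintSystem:
    """Derive the equilibrium constraints of a model.

    Parameters
    ----------
    dependent:
        Optional pinned list of dependent process names (length = rank);
        must index a full-rank column subset of the increment matrix.
        Default: pivoted-QR choice.
    """
    D = model.increment_matrix().astype(float)
    n, K = D.shape
    sv = np.linalg.svd(D, compute_uv=False)
    rank = int(np.sum(sv > RANK_TOL * (sv[0] if sv.size else 1.0)))

    if dependent is not None:
        dep = tuple(model.process_index(nm) for nm in dependent)
        if len(dep) != rank:
            raise ValueError(
                f"pinned dependent set has {len(dep)} rates but rank is {rank}")
    else:
        # QR with column pivoting: first `rank` pivot columns are a
        # well-conditioned dependent set.
        _, _, piv = scipy.linalg.qr(D, pivoting=True)
        dep = tuple(sorted(int(i) for i in piv[:rank]))
    free = tuple(i for i in range(K) if i not in dep)

    D_dep = D[:, list(dep)]
    if np.linalg.matrix_rank(D_dep, tol=RANK_TOL * max(sv[0], 1.0)) < rank:
        raise ValueError("dependent set does not span the constraint space; "
                         "choose a different partition")
    # Q_dep = -pinv(D_dep) @ D_free @ Q_free. Columns of D_free lie in the
    # column space of D_dep, so lstsq residuals are zero (asserted).
    D_free = D[:, list(free)]
    coeff, *_ = np.linalg.lstsq(-D_dep, D_free, rcond=None)
    resid = D_dep @ (-coeff) - D_free
    if np.abs(resid).max() > 1e-8:
        raise ValueError("inconsistent partition: free columns leave the "
                         "span of the dependent columns")
    coeff[np.abs(coeff) < 1e-12] = 0.0
    return ConstraintSystem(matrix=D, rank=rank,
                            process_names=model.process_names,
                            free_indices=free, dependent_indices=dep,
                            coefficients=coeff)


def constraint_rank(model: LineageModel) -> int:
    """Number of independent equilibrium constraints (rank of increments)."""
    return constraint_system(model).rank


def solve_rates(model: LineageModel,
                free_assignments: Mapping[str, float],
                dependent: Sequence[str] | None = None) -> RateSolution:
    """Solve for all K equilibrium rates given values for the free ones.

    ``free_assignments`` must cover exactly the free rates of the
    constraint system (with the same pinned partition, if any) and be
    nonnegative. The result satisfies ``drift(i*) = 0``; ``feasible`` is
    False if any dependent rate comes out negative.
    """
    cs = constraint_system(model, dependent=dependent)
    want = set(cs.free_names)
    got = set(free_assignments)
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        raise ValueError(
            f"free assignment mismatch: missing {missing}, unexpected {extra}")
    q_free = np.array([float(free_assignments[n]) for n in cs.free_names])
    if (q_free < 0).any():
        bad = [n for n, v in zip(cs.free_names, q_free) if v < 0]
        raise ValueError(f"negative free rate(s): {bad}")
    q_dep = cs.coefficients @ q_free
    rates = np.empty(model.n_processes)
    rates[list(cs.free_indices)] = q_free
    rates[list(cs.dependent_indices)] = q_dep
    feasible = bool((q_dep >= -1e-12).all())
    return RateSolution(rates=rates, feasible=feasible,
                        process_names=model.process_names)
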