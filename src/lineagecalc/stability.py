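"""Local stability and robustness of the homeostatic equilibrium.

The Jacobian of the deterministic drift at equilibrium combines controls
with increments:

    J[m, j] = sum_k (dQ_k/di_j) * increment_k[m]

i.e. ``J = D @ C`` with ``D`` the n x K increment matrix and ``C`` the
K x n control matrix. The equilibrium is locally stable iff every
eigenvalue of ``J`` has a strictly negative real part; the same
eigenvalues also govern the decay of second-moment perturbations, so one
matrix answers both the deterministic and the fluctuation question.

Robustness is quantified empirically: fix the control *topology* (which
population controls which process, and with what sign) and sample the
control magnitudes uniformly from given intervals; the stable fraction of
draws measures how much of sign-respecting parameter space is stable. A
sign-stable topology scores 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import LineageModel, ModelValidationError

__all__ = ["StabilityReport", "RobustnessResult", "jacobian",
           "stability_report", "robustness_fraction"]

#: Strictness tolerance: eigenvalue real parts must be below -STABILITY_TOL.
#: Marginal (zero) eigenvalues are reported as not stable.
STABILITY_TOL = 1e-12


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: np.ndarray      # complex, length n
    stable: bool
    margin: float                # max real part

    def to_dict(self) -> dict:
        return {
            "stable": self.stable,
            "margin": self.margin,
            "eigenvalues": [(float(ev.real), float(ev.imag))
                            for ev in self.eigenvalues],
            "jacobian": self.jacobian.tolist(),
        }


@dataclass(frozen=True)
class RobustnessResult:
    n_samples: int
    n_stable: int
    seed: int
    bounds: dict

    @property
    def fraction(self) -> float:
        return self.n_stable / self.n_samples

    def to_dict(self) -> dict:
        return {"n_samples": self.n_samples, "n_stable": self.n_stable,
                "fraction": self.fraction, "seed": self.seed,
                "bounds": {f"{p}:{c}": list(iv)
                           for (p, c), iv in self.bounds.items()}}


def jacobian(model: LineageModel) -> np.ndarray:
    """Equilibrium Jacobian ``J = D @ C`` (depends only on controls)."""
    return model.increment_matrix().astype(float) @ model.control_matrix()


def _report_for(J: np.ndarray) -> StabilityReport:
    eig = np.linalg.eigvals(J)
    margin = float(eig.real.max())
    return StabilityReport(jacobian=J, eigenvalues=eig,
                           stable=margin < -STABILITY_TOL, margin=margin)


def stability_report(model: LineageModel) -> StabilityReport:
    """Eigenvalues of the Jacobian and a strict stability verdict."""
    return _report_for(jacobian(model))


def robustness_fraction(model: LineageModel,
                        bounds: Mapping[tuple[str, str], tuple[float, float]],
                        n_samples: int,
                        seed: int) -> RobustnessResult:
    """Stable fraction over uniform control draws with fixed topology.

    Parameters
    ----------
    bounds:
        Map ``(process_name, compartment_name) -> (lo, hi)`` sampling
        interval for each varied control. Controls not listed keep their
        model value. Each interval must respect the process's sign
        annotation for that compartment, if one is declared.
    n_samples, seed:
        Draw count (>= 1) and RNG seed; results are reproducible
        bit-for-bit for a fixed (seed, n_samples, bounds).
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    entries = []
    for (pname, cname), (lo, hi) in bounds.items():
        k = model.process_index(pname)
        if cname not in model.compartment_names:
            raise ModelValidationError(
                f"bounds reference undeclared compartment '{cname}'")
        j = model.compartment_names.index(cname)
        if lo > hi:
            raise ValueError(f"empty interval for {pname}:{cname}")
        sign = model.processes[k].control_signs.get(cname)
        if sign == "-" and hi > 0 or sign == "+" and lo < 0:
            raise ModelValidationError(
                f"interval [{lo}, {hi}] for {pname}:{cname} violates its "
                f"'{sign}' sign annotation")
        entries.append((k, j, lo, hi))

    D = model.increment_matrix().astype(float)
    C0 = model.control_matrix()
    rng = np.random.default_rng(seed)
    n_stable = 0
    for _ in range(n_samples):
        C = C0.copy()
        for k, j, lo, hi in entries:
            C[k, j] = rng.uniform(lo, hi)
        if _report_for(D @ C).stable:
            n_stable += 1
    return RobustnessResult(n_samples=n_samples, n_stable=n_stable,
                            seed=seed, bounds=dict(bounds))
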