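"""Stationary second moments of compartment counts (linear noise regime).

Near a stable equilibrium, the fluctuations of the count vector follow an
Ornstein-Uhlenbeck process with drift matrix ``J`` (the Jacobian) and
diffusion matrix

    S[p, q] = sum_k Q_k0 * increment_k[p] * increment_k[q]

— an equilibrium-rate-weighted sum of rank-1 outer products of the
process increments, hence symmetric positive semidefinite. The stationary
covariance matrix ``Y`` solves the continuous Lyapunov equation

    J Y + Y J^T = -S,

equivalently the flattened linear system ``W yvec = -svec`` with
``W = J (+) J`` the Kronecker sum, or the matrix integral
``Y = int_0^inf exp(J t) S exp(J^T t) dt`` (convergent exactly when J is
stable). All three routes are implemented; the Lyapunov solve is the
default and the other two serve as independent cross-checks.

Flattening convention: row-major pairing (1,1), (1,2), ..., (n,n), i.e.
``yvec = Y.flatten()``; ``W = kron(J, I) + kron(I, J)`` matches it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.linalg

from .model import LineageModel
from .stability import jacobian, stability_report

__all__ = ["DiffusionMatrix", "CovarianceResult", "UnstableModelError",
           "diffusion_matrix", "kronecker_sum", "stationary_covariance",
           "covariance_integral_oracle"]


class UnstableModelError(RuntimeError):
    """No stationary covariance exists: the Jacobian is not stable."""


@dataclass(frozen=True)
class DiffusionMatrix:
    S: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening svec = (s_11, s_12, ..., s_nn)."""
        return self.S.flatten()


@dataclass(frozen=True)
class CovarianceResult:
    """Stationary covariance Y with the J and S that produced it."""

    Y: np.ndarray
    method: str                  # "lyapunov" | "linear-solve" | "integral"
    J: np.ndarray
    S: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.Y.flatten()

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.Y).copy()

    def to_dict(self, names: tuple[str, ...] | None = None) -> dict:
        d = {"method": self.method, "covariance": self.Y.tolist(),
             "variances": self.variances.tolist()}
        if names is not None:
            d["compartments"] = list(names)
        return d


def diffusion_matrix(model: LineageModel) -> DiffusionMatrix:
    """S = D diag(Q0) D^T; requires all equilibrium rates resolved."""
    D = model.increment_matrix().astype(float)
    Q0 = model.equilibrium_rate_vector()
    S = (D * Q0) @ D.T
    return DiffusionMatrix(S=0.5 * (S + S.T))


def kronecker_sum(J: np.ndarray) -> np.ndarray:
    """W = J (+) J = kron(J, I) + kron(I, J) (row-major flattening).

    The eigenvalues of W are all pairwise sums of eigenvalues of J, so W
    is invertible exactly when no two eigenvalues of J sum to zero — in
    particular whenever J is stable.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"J must be square, got shape {J.shape}")
    I = np.eye(J.shape[0])
    return np.kron(J, I) + np.kron(I, J)


def _check_stable(model: LineageModel) -> np.ndarray:
    rep = stability_report(model)
    if not rep.stable:
        raise UnstableModelError(
            f"no stationary covariance: Jacobian margin {rep.margin:.3g} >= 0")
    return rep.jacobian


def stationary_covariance(model: LineageModel,
                          method: str = "lyapunov") -> CovarianceResult:
    """Solve J Y + Y J^T = -S for the stationary covariance.

    ``method`` selects the route: ``"lyapunov"`` (dense Bartels-Stewart,
    default), ``"linear-solve"`` (the flattened n^2 system), or
    ``"integral"`` (matrix-exponential quadrature). The result is
    symmetrised to remove round-off asymmetry.
    """
    J = _check_stable(model)
    S = diffusion_matrix(model).S
    if method == "lyapunov":
        Y = scipy.linalg.solve_continuous_lyapunov(J, -S)
    elif method == "linear-solve":
        W = kronecker_sum(J)
        cond = np.linalg.cond(W)
        if cond > 1e12:
            warnings.warn(f"flattened covariance system is ill-conditioned "
                          f"(cond ~ {cond:.2g})", RuntimeWarning)
        Y = np.linalg.solve(W, -S.flatten()).reshape(J.shape)
    elif method == "integral":
        return covariance_integral_oracle(model)
    else:
        raise ValueError(f"unknown method {method!r}")
    Y = 0.5 * (Y + Y.T)
    return CovarianceResult(Y=Y, method=method, J=J, S=S)


def covariance_integral_oracle(model: LineageModel,
                               t_max: float | None = None,
                               tol: float = 1e-10) -> CovarianceResult:
    """Quadrature of Y = int_0^inf exp(Jt) S exp(J^T t) dt.

    Kept deliberately independent of the algebraic solvers so it can act
    as an oracle. ``t_max`` defaults to the time at which the integrand
    envelope exp(2*margin*t) has decayed below ``tol``; the tail beyond
    t_max is bounded by tol * ||S|| / (2|margin|) and neglected.
    """
    J = _check_stable(model)
    S = diffusion_matrix(model).S
    margin = stability_report(model).margin  # < 0 here
    if t_max is None:
        t_max = float(np.log(1.0 / tol) / (2.0 * abs(margin)))

    def integrand(t: float) -> np.ndarray:
        E = scipy.linalg.expm(J * t)
        return (E @ S @ E.T).flatten()

    vec, _ = scipy.integrate.quad_vec(integrand, 0.0, t_max,
                                      epsabs=tol, epsrel=tol)
    Y = vec.reshape(J.shape)
    Y = 0.5 * (Y + Y.T)
    return CovarianceResult(Y=Y, method="integral", J=J, S=S)
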