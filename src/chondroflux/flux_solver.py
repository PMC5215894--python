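"""Weighted bounded-variable least-squares (BVLS) estimation of average fluxes.

The average flux vector v over an interval satisfies S v = delta as well as
the data allow: we minimize ``|| W S v - W delta ||_2`` with ``W = diag(w)``
(each row of S and its accumulation multiplied by that metabolite's weight),
subject to ``v_i >= 0`` for irreversible reactions.  The weighted problem is
a convex bounded-variable least-squares program; any solver reaching its
global optimum is equivalent, and optimality is certified by the KKT
conditions at the returned point.

Unmeasured internal metabolites are constrained to zero accumulation either
softly (a weighted row with delta = 0 at the median measured weight, the
default, which keeps the problem a pure BVLS) or as hard equality rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize, LinearConstraint
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .accumulation import AccumulationVector
from .network import StoichiometricNetwork

__all__ = [
    "FluxProblem",
    "FluxProfile",
    "FluxBVLS",
    "assemble_problem",
    "solve_flux",
    "residual_report",
    "kkt_violation",
]


@dataclass
class FluxProblem:
    """Weighted BVLS instance: minimize ||S_w v - delta_w|| over bounds."""

    S: np.ndarray               # raw stoichiometric matrix (rows kept in reduction)
    delta: np.ndarray           # raw accumulation rates
    weights: np.ndarray         # per-row weights w_i (row multipliers)
    lower_bounds: np.ndarray    # 0 for irreversible reactions, -inf otherwise
    upper_bounds: np.ndarray    # +inf at the solver level
    equality_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    metabolite_ids: list[str] | None = None
    reaction_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        m, n = self.S.shape
        if self.delta.shape != (m,) or self.weights.shape != (m,):
            raise ValueError("delta/weights length does not match matrix rows")
        if self.lower_bounds.shape != (n,) or self.upper_bounds.shape != (n,):
            raise ValueError("bounds length does not match number of reactions")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")

    @property
    def S_w(self) -> np.ndarray:
        return self.S * self.weights[:, None]

    @property
    def delta_w(self) -> np.ndarray:
        return self.delta * self.weights


@dataclass
class FluxProfile:
    """Solved flux vector with residual diagnostics."""

    v: np.ndarray
    objective: float            # || S_w v - delta_w ||_2
    residuals_raw: np.ndarray   # S v - delta
    residuals_weighted: np.ndarray
    converged: bool
    tol: float
    message: str = ""
    reaction_ids: list[str] | None = None
    metabolite_ids: list[str] | None = None

    def as_series(self) -> pd.Series:
        idx = self.reaction_ids if self.reaction_ids is not None else range(len(self.v))
        return pd.Series(self.v, index=idx, name="flux")


class FluxBVLS(RegressorMixin, BaseEstimator):
    """Bounded-variable least squares as a scikit-learn regressor.

    ``fit(X, y, sample_weight)`` minimizes ``|| diag(sample_weight) (X v - y) ||_2``
    subject to box bounds on the coefficients.  Note the weights multiply the
    *rows* (residuals), not the squared residuals — this matches the
    inverse-variance row-scaling convention of the flux pipeline.

    Parameters
    ----------
    lower_bounds, upper_bounds : array-like or scalar
        Per-coefficient bounds; defaults are unbounded.  For a flux problem
        the lower bound is 0 for irreversible reactions and -inf otherwise.
    tol : float
        Optimality tolerance passed to the solver.
    max_iter : int or None
        Iteration cap; defaults to 10 * n_features**2.

    Attributes
    ----------
    flux_ : ndarray — the fitted coefficient (flux) vector, also ``coef_``.
    objective_ : float — weighted residual two-norm at the optimum.
    converged_ : bool
    """

    def __init__(self, lower_bounds=None, upper_bounds=None, tol: float = 1e-10,
                 max_iter: int | None = None):
        self.lower_bounds = lower_bounds
        self.upper_bounds = upper_bounds
        self.tol = tol
        self.max_iter = max_iter

    def _bounds(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(n, -np.inf) if self.lower_bounds is None else np.broadcast_to(
            np.asarray(self.lower_bounds, dtype=float), (n,)).copy()
        ub = np.full(n, np.inf) if self.upper_bounds is None else np.broadcast_to(
            np.asarray(self.upper_bounds, dtype=float), (n,)).copy()
        return lb, ub

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be 2-D with y matching its row count")
        w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
        if w.shape != (X.shape[0],):
            raise ValueError("sample_weight length mismatch")
        lb, ub = self._bounds(X.shape[1])
        max_iter = self.max_iter if self.max_iter is not None else 10 * X.shape[1] ** 2
        res = lsq_linear(X * w[:, None], y * w, bounds=(lb, ub), method="bvls",
                         tol=self.tol, max_iter=max_iter)
        if res.status < 1 and not res.success:
            raise RuntimeError(f"BVLS did not converge: {res.message}; best iterate kept")
        # clip roundoff-level bound violations
        self.flux_ = np.clip(res.x, lb, ub)
        self.coef_ = self.flux_
        self.objective_ = float(np.linalg.norm((X * w[:, None]) @ self.flux_ - y * w))
        self.converged_ = bool(res.success)
        self.message_ = res.message
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "flux_")
        return np.asarray(X, dtype=float) @ self.flux_


def assemble_problem(
    net: StoichiometricNetwork,
    acc: AccumulationVector,
    hard_zero: bool = False,
) -> FluxProblem:
    """Build the weighted BVLS instance from a reduced network and an
    accumulation vector.

    Constrained-zero rows without a weight receive the median measured weight
    (soft, default) or become hard equality rows; ETC rows already carry the
    lowest measured weight from :func:`chondroflux.accumulation.compute_weights`.
    """
    if net.metabolite_ids != acc.metabolite_ids:
        raise ValueError("network rows and accumulation metabolites do not align")
    S = net.S
    delta = acc.delta.copy()
    weights = acc.weight.copy()
    constrained = acc.constrained_zero

    measured_w = weights[~constrained & np.isfinite(weights)]
    if measured_w.size == 0:
        raise ValueError("no measured weights available")
    median_w = float(np.median(measured_w))

    fill = constrained & ~np.isfinite(weights)
    weights[fill] = median_w
    delta[constrained] = 0.0
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("nonpositive or missing weight after assembly")

    eq_rows = np.flatnonzero(constrained) if hard_zero else np.array([], dtype=int)
    lb = np.where(net.irreversible_mask, 0.0, -np.inf)
    ub = np.full(S.shape[1], np.inf)
    return FluxProblem(S=S, delta=delta, weights=weights, lower_bounds=lb,
                       upper_bounds=ub, equality_rows=eq_rows,
                       metabolite_ids=net.metabolite_ids, reaction_ids=net.reaction_ids)


def _solve_hard(problem: FluxProblem, tol: float) -> np.ndarray:
    """Equality-constrained weighted bounded least squares (convex QP) via
    trust-constr with exact derivatives, warm-started from the soft BVLS
    solution.  The objective is normalized to unit scale so the optimizer's
    tolerances are meaningful regardless of the weight magnitudes."""
    from scipy.optimize import Bounds

    A, b = problem.S_w, problem.delta_w
    free = np.ones(len(b), dtype=bool)
    free[problem.equality_rows] = False
    scale = max(np.linalg.norm(b[free]), 1.0)
    Af, bf = A[free] / scale, b[free] / scale
    E = problem.S[problem.equality_rows]
    if len(E):
        # conjugate carrier pairs (e.g. oxidized/reduced forms) make equality
        # rows linearly dependent; pass an equivalent full-rank basis instead
        _, sv, Vt = np.linalg.svd(E, full_matrices=False)
        rank = int(np.sum(sv > 1e-12 * sv[0]))
        E = Vt[:rank]

    est = FluxBVLS(lower_bounds=problem.lower_bounds, upper_bounds=problem.upper_bounds, tol=tol)
    x0 = est.fit(A, b).flux_

    H = Af.T @ Af
    g0 = -Af.T @ bf

    def fun(v):
        r = Af @ v - bf
        return 0.5 * float(r @ r)

    res = minimize(
        fun, x0, jac=lambda v: H @ v + g0, hess=lambda v: H,
        method="trust-constr",
        bounds=Bounds(problem.lower_bounds, problem.upper_bounds),
        constraints=[LinearConstraint(E, 0.0, 0.0)] if len(E) else [],
        options={"maxiter": 2000, "gtol": max(tol, 1e-12), "xtol": 1e-14},
    )
    if res.status not in (1, 2):
        raise RuntimeError(f"hard-constrained solve failed: {res.message}")
    if len(E) and np.max(np.abs(E @ res.x)) > 1e-6:
        raise RuntimeError("equality rows infeasible at returned point")
    return np.clip(res.x, problem.lower_bounds, problem.upper_bounds)


def solve_flux(problem: FluxProblem, tol: float = 1e-10) -> FluxProfile:
    """Solve the weighted BVLS (global optimum of the convex program)."""
    if len(problem.equality_rows):
        v = _solve_hard(problem, tol)
        converged, message = True, "SLSQP with hard equality rows"
    else:
        est = FluxBVLS(lower_bounds=problem.lower_bounds,
                       upper_bounds=problem.upper_bounds, tol=tol)
        est.fit(problem.S_w, problem.delta_w)
        v, converged, message = est.flux_, est.converged_, est.message_
    raw = problem.S @ v - problem.delta
    weighted = problem.weights * raw
    return FluxProfile(
        v=v, objective=float(np.linalg.norm(problem.S_w @ v - problem.delta_w)),
        residuals_raw=raw, residuals_weighted=weighted, converged=converged,
        tol=tol, message=message, reaction_ids=problem.reaction_ids,
        metabolite_ids=problem.metabolite_ids,
    )


def residual_report(profile: FluxProfile) -> pd.DataFrame:
    """Per-metabolite residual table, largest |raw residual| first."""
    idx = profile.metabolite_ids if profile.metabolite_ids is not None else range(
        len(profile.residuals_raw))
    df = pd.DataFrame({
        "residual_raw": profile.residuals_raw,
        "residual_weighted": profile.residuals_weighted,
    }, index=pd.Index(idx, name="metabolite_id"))
    return df.reindex(df["residual_raw"].abs().sort_values(ascending=False).index)


def kkt_violation(problem: FluxProblem, v: np.ndarray) -> float:
    """Max violation of the KKT optimality conditions at v.

    For g = gradient of 0.5 ||S_w v - delta_w||^2: free variables need g = 0,
    variables at the lower bound need g >= 0, at the upper bound g <= 0.
    """
    g = problem.S_w.T @ (problem.S_w @ v - problem.delta_w)
    scale = max(1.0, float(np.linalg.norm(problem.S_w.T @ problem.delta_w)))
    atol = 1e-8 * scale
    viol = 0.0
    for j in range(len(v)):
        at_lb = v[j] <= problem.lower_bounds[j] + atol
        at_ub = v[j] >= problem.upper_bounds[j] - atol
        if at_lb and not at_ub:
            viol = max(viol, max(0.0, -g[j]))
        elif at_ub and not at_lb:
            viol = max(viol, max(0.0, g[j]))
        elif not at_lb and not at_ub:
            viol = max(viol, abs(g[j]))
    return float(viol)
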