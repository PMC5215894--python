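"""Independent brute-force oracles used to cross-check the solvers.

These are deliberately naive (exhaustive enumeration, closed forms, direct
tallies) and share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def active_set_bvls(A: np.ndarray, b: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """Global minimum of ||A x - b|| over box bounds by exhaustive active-set
    enumeration.

    Every variable is either free, pinned at its lower bound, or pinned at its
    upper bound; for each of the <= 3^n combinations, solve the reduced
    unconstrained least squares for the free variables, keep feasible
    candidates, and return the best (objective, x).
    """
    n = A.shape[1]
    best_obj, best_x = np.inf, None
    states_per_var = [
        [s for s in ("free", "lo", "hi")
         if (s != "lo" or np.isfinite(lb[j])) and (s != "hi" or np.isfinite(ub[j]))]
        for j in range(n)
    ]
    for states in itertools.product(*states_per_var):
        x = np.zeros(n)
        fixed = np.zeros(n, dtype=bool)
        for j, s in enumerate(states):
            if s == "lo":
                x[j], fixed[j] = lb[j], True
            elif s == "hi":
                x[j], fixed[j] = ub[j], True
        free = ~fixed
        rhs = b - A[:, fixed] @ x[fixed]
        if free.any():
            sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            x[free] = sol
        if np.any(x < lb - 1e-9) or np.any(x > ub + 1e-9):
            continue
        obj = float(np.linalg.norm(A @ x - b))
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x.copy()
    return best_obj, best_x


def enumerate_lp_vertices(c: np.ndarray, A_eq: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    """Optimal value of min c.x s.t. A_eq x = 0, lb <= x <= ub by enumerating
    basic feasible solutions (m free variables solved from the equalities, the
    rest pinned at a bound)."""
    m, n = A_eq.shape
    best = np.inf
    best_x = None
    for free in itertools.combinations(range(n), m):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        B = A_eq[:, free]
        if np.linalg.matrix_rank(B) < m:
            continue
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            x = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                x[j] = val
            rhs = -A_eq[:, fixed] @ x[fixed] if fixed else np.zeros(m)
            x[free] = np.linalg.solve(B, rhs)
            if np.any(x < lb - 1e-9) or np.any(x > ub + 1e-9):
                continue
            val = float(c @ x)
            if val < best - 1e-12:
                best, best_x = val, x.copy()
    return best, best_x


def tally_precursors(seq: str) -> dict[str, float]:
    """Residue-by-residue precursor tally, written independently of the
    package's mapping machinery (shares only the biological assignment)."""
    counts = {"3PG": 0.0, "PYR": 0.0, "AKG": 0.0, "OAA": 0.0}
    for ch in seq.upper():
        if ch in "SGC":
            counts["3PG"] += 1
        elif ch in "AVL":
            counts["PYR"] += 1
        elif ch == "I":
            counts["PYR"] += 0.5
            counts["OAA"] += 0.5
        elif ch in "EQPR":
            counts["AKG"] += 1
        elif ch in "DNTMK":
            counts["OAA"] += 1
        elif ch in "FYWH":
            pass
        else:
            raise ValueError(f"unexpected residue {ch!r}")
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items() if v > 0}


def pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
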