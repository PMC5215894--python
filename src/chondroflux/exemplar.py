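"""Synthesis-maximizing exemplar flux profiles by linear programming.

An exemplar answers: if central metabolism were optimized purely to produce a
given biosynthetic product, what would the flux distribution look like?  It
solves

    min  c^T v        (c = 0 except -1 at the synthesis column)
    s.t. S_I v = 0    (internal metabolites balanced: feasible pathways)
         A v  >= 0    (irreversible reactions run forward)
         v   <= cap   (unit flux cap; the program is otherwise unbounded)

External metabolites (net substrates/products such as glucose or lactate) are
left unconstrained.  A symmetric lower cap of ``-cap`` is applied to
reversible reactions: the published formulation caps only the maximum, but
without a lower cap reversible loops are unbounded below, so the symmetric
cap is required for well-posedness and is documented as such.

LPs can have many optimal vertices; for a deterministic, solver-independent
answer the reported profile is the minimum-l1-norm point among the optima
(a secondary LP at the fixed optimal objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .flux_solver import FluxProfile
from .network import StoichiometricNetwork

__all__ = [
    "ExemplarLP",
    "assemble_exemplar_lp",
    "max_synthesis_profile",
    "profile_shape_features",
    "compare_profiles",
]

#: precursor -> (pathway, reactions upstream of it, reactions downstream)
_PRECURSOR_SPLITS = {
    "3PG": ("G", ["G1", "G2", "G3", "G4", "G5", "G6", "G7"], ["G8", "G9", "G10"]),
    "PYR": ("G", ["G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8", "G9"], ["G10"]),
    "AKG": ("TCA", ["TCA1", "TCA2", "TCA3", "TCA4"], ["TCA5", "TCA6", "TCA7", "TCA8", "TCA9"]),
    "OAA": ("TCA", ["TCA1", "TCA2", "TCA3", "TCA4", "TCA5", "TCA6", "TCA7", "TCA8"], ["TCA9"]),
}


@dataclass
class ExemplarLP:
    c: np.ndarray          # 0 everywhere, -1 at the synthesis column
    S_I: np.ndarray        # internal-metabolite rows of S
    irreversible: np.ndarray  # boolean mask (the diagonal of A)
    upper_cap: float
    reaction_ids: list[str]
    internal_ids: list[str]

    def __post_init__(self) -> None:
        if np.count_nonzero(self.c == -1.0) != 1 or np.count_nonzero(self.c) != 1:
            raise ValueError("objective must be -1 at exactly one synthesis column")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(0.0 if irr else -self.upper_cap, self.upper_cap)
                for irr in self.irreversible]


def assemble_exemplar_lp(net: StoichiometricNetwork, synthesis_id: str,
                         upper_cap: float = 1.0) -> ExemplarLP:
    if synthesis_id not in net.reaction_ids:
        raise ValueError(f"unknown synthesis reaction {synthesis_id!r}")
    if net.reaction(synthesis_id).pathway != "SYN":
        raise ValueError(f"{synthesis_id!r} is not a synthesis (SYN) column")
    c = np.zeros(len(net.reactions))
    c[net.reaction_ids.index(synthesis_id)] = -1.0
    internal = net.internal_mask
    return ExemplarLP(
        c=c, S_I=net.S[internal], irreversible=net.irreversible_mask,
        upper_cap=upper_cap, reaction_ids=net.reaction_ids,
        internal_ids=[m.id for m, keep in zip(net.metabolites, internal) if keep],
    )


def _solve_lp(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def max_synthesis_profile(net: StoichiometricNetwork, synthesis_id: str,
                          upper_cap: float = 1.0) -> FluxProfile:
    """Flux profile maximizing the named synthesis reaction.

    The zero vector is always feasible, so an infeasible LP indicates
    malformed constraints and raises.  Among the optimal vertices the
    minimum-l1-norm one is returned (deterministic tie-break).
    """
    lp = assemble_exemplar_lp(net, synthesis_id, upper_cap)
    n = len(lp.c)
    res = _solve_lp(lp.c, lp.S_I, np.zeros(lp.S_I.shape[0]), lp.bounds)
    if res.status == 2:
        raise RuntimeError("exemplar LP infeasible: malformed constraints "
                           "(v = 0 should always be feasible)")
    if res.status != 0:
        raise RuntimeError(f"exemplar LP failed: {res.message}")
    opt = float(res.fun)

    # tie-break: minimize sum(t), t >= |v|, subject to c^T v = opt
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([lp.S_I, np.zeros_like(lp.S_I)])
    A_eq = np.vstack([A_eq, np.concatenate([lp.c, np.zeros(n)])])
    b_eq = np.concatenate([np.zeros(lp.S_I.shape[0]), [opt]])
    # t - v >= 0 and t + v >= 0  ->  A_ub x <= 0 with x = (v, t)
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    bounds2 = lp.bounds + [(0.0, lp.upper_cap)] * n
    res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds2, method="highs")
    v = res2.x[:n] if res2.status == 0 else res.x

    balances = lp.S_I @ v
    return FluxProfile(
        v=v, objective=opt, residuals_raw=balances,
        residuals_weighted=balances, converged=True, tol=1e-9,
        message=f"exemplar LP for {synthesis_id}", reaction_ids=lp.reaction_ids,
        metabolite_ids=lp.internal_ids,
    )


def profile_shape_features(profile: FluxProfile, net: StoichiometricNetwork) -> dict:
    """Pathway-level shape summary of a flux profile.

    Reports, for each protein precursor, the mean flux of the reactions
    upstream versus downstream of it in its pathway (protein-optimized
    metabolism shows higher activity before the precursors than after),
    pathway flux totals (mean |v| per pathway), and the max-min flux spread
    within glycolysis and the TCA cycle (lipid-optimized metabolism keeps
    these distributions more even).
    """
    v = profile.as_series()
    feats: dict[str, float] = {}
    for prec, (pathway, up, down) in _PRECURSOR_SPLITS.items():
        up = [r for r in up if r in v.index]
        down = [r for r in down if r in v.index]
        if not up or not down:
            continue
        feats[f"{prec}_upstream_mean"] = float(v[up].mean())
        feats[f"{prec}_downstream_mean"] = float(v[down].mean())
    for pathway in sorted({r.pathway for r in net.reactions}):
        ids = [r.id for r in net.reactions if r.pathway == pathway]
        feats[f"{pathway}_mean_abs_flux"] = float(v[ids].abs().mean())
        if pathway in ("G", "TCA"):
            feats[f"{pathway}_flux_spread"] = float(v[ids].max() - v[ids].min())
    return feats


def compare_profiles(p1: FluxProfile, p2: FluxProfile) -> tuple[float, np.ndarray]:
    """Relative distance ||v1 - v2|| / min(||v1||, ||v2||) plus per-reaction
    absolute differences."""
    if p1.reaction_ids is not None and p2.reaction_ids is not None \
            and p1.reaction_ids != p2.reaction_ids:
        raise ValueError("profiles have different reaction orderings")
    v1, v2 = np.asarray(p1.v), np.asarray(p2.v)
    if v1.shape != v2.shape:
        raise ValueError("profiles have different lengths")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if min(n1, n2) == 0:
        raise ValueError("relative distance undefined for a zero-norm profile")
    return float(np.linalg.norm(v1 - v2) / min(n1, n2)), np.abs(v1 - v2)
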