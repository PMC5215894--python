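"""Stoichiometric model of mammalian central energy metabolism.

The network covers glycolysis (G), pyruvate processing into acetyl-CoA (PYP),
the TCA cycle (TCA), the pentose phosphate pathway (PPP), the electron
transport chain (ETC), anaplerotic reactions (AP), and lactate (LDH) and
glutamine/glutamate (GDH) dehydrogenase entry points.  Metabolites are
classified as *internal* (pathway intermediates, balanced at steady state in
the exemplar linear programs) or *external* (net substrates/products of the
network, left unconstrained), and flagged *measurable* when they are
detectable in a targeted LC-MS experiment.

The matrix convention is the usual one in constraint-based modeling: rows are
metabolites, columns are reactions, consumed species carry negative
coefficients and produced species positive ones, so ``S @ v`` is the vector of
net accumulation rates under flux vector ``v``.  Reversible reactions take the
drawn pathway direction as forward; a negative flux means the reaction runs
against it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricNetwork",
    "SynthesisReaction",
    "NetworkParseError",
    "parse_network",
    "write_network",
    "build_full_network",
    "reduce_to_measured",
    "synthesis_from_sequence",
    "lipid_synthesis_reaction",
    "add_synthesis_reaction",
    "packaged_measured_ids",
    "RESIDUE_PRECURSORS",
    "PROTEIN_PRECURSORS",
]

PROTEIN_PRECURSORS = ("3PG", "PYR", "AKG", "OAA")

#: Biosynthetic-family assignment of the twenty standard residues to the four
#: central-metabolic protein precursors.  Isoleucine draws on both the
#: pyruvate and the aspartate (oxaloacetate) families and is split evenly.
#: Aromatic residues and histidine originate outside these four precursors
#: (chorismate / PRPP routes) and carry no coefficient; callers receive a
#: count of skipped residues.
RESIDUE_PRECURSORS: dict[str, dict[str, float]] = {
    "S": {"3PG": 1.0}, "G": {"3PG": 1.0}, "C": {"3PG": 1.0},
    "A": {"PYR": 1.0}, "V": {"PYR": 1.0}, "L": {"PYR": 1.0},
    "I": {"PYR": 0.5, "OAA": 0.5},
    "E": {"AKG": 1.0}, "Q": {"AKG": 1.0}, "P": {"AKG": 1.0}, "R": {"AKG": 1.0},
    "D": {"OAA": 1.0}, "N": {"OAA": 1.0}, "T": {"OAA": 1.0},
    "M": {"OAA": 1.0}, "K": {"OAA": 1.0},
    "F": {}, "Y": {}, "W": {}, "H": {},
}


class NetworkParseError(ValueError):
    """Raised when a network definition file cannot be parsed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    role: str = "internal"  # "internal" | "external"
    measurable: bool = True
    etc_member: bool = False
    #: set by reduce_to_measured: accumulation pinned to zero
    constrained_zero: bool = False
    #: set by reduce_to_measured: residual gets the lowest weight (ETC carriers)
    lowest_weight: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("internal", "external"):
            raise ValueError(f"metabolite {self.id!r}: bad role {self.role!r}")
        if self.etc_member and (self.role != "internal" or self.measurable):
            raise ValueError(
                f"metabolite {self.id!r}: ETC carriers must be internal and unmeasurable"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    pathway: str
    reversible: bool
    stoichiometry: Mapping[str, float]

    def __post_init__(self) -> None:
        coeffs = {k: float(v) for k, v in self.stoichiometry.items() if v != 0}
        object.__setattr__(self, "stoichiometry", coeffs)
        if not coeffs:
            raise ValueError(f"reaction {self.id!r} has no nonzero coefficients")


@dataclass(frozen=True)
class SynthesisReaction:
    """Precursor demand of one biosynthetic product (a protein or lipid).

    Coefficients are positive consumption amounts; under the default
    ``fraction-of-total`` normalization they sum to one, so the column encodes
    the ratiometric precursor composition of a unit of product.
    """

    product_name: str
    coefficients: Mapping[str, float]
    normalization: str = "fraction-of-total"  # or "per-molecule"
    skipped_residues: int = 0

    def __post_init__(self) -> None:
        coeffs = dict(self.coefficients)
        if not coeffs:
            raise ValueError(f"synthesis reaction {self.product_name!r} is empty")
        if any(c <= 0 for c in coeffs.values()):
            raise ValueError("synthesis coefficients must be strictly positive")
        object.__setattr__(self, "coefficients", coeffs)


@dataclass
class StoichiometricNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        known = set(ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise NetworkParseError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(unknown)}"
                )

    # -- matrix views -----------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix, metabolites x reactions."""
        row = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[row[met], j] = coef
        return S

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.metabolite_ids, columns=self.reaction_ids)

    @property
    def irreversible_mask(self) -> np.ndarray:
        return np.array([not r.reversible for r in self.reactions])

    @property
    def internal_mask(self) -> np.ndarray:
        return np.array([m.role == "internal" for m in self.metabolites])

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


# ---------------------------------------------------------------------------
# parsing / serialization

_ARROWS = ("<->", "->")


def _parse_equation(eq: str, known: set[str], where: str) -> tuple[dict[str, float], bool]:
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise NetworkParseError(f"{where}: no reaction arrow in {eq!r}")
    reversible = arrow == "<->"
    lhs, rhs = eq.split(arrow)
    coeffs: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            raise NetworkParseError(f"{where}: empty reaction side in {eq!r}")
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise NetworkParseError(f"{where}: bad coefficient {parts[0]!r}") from exc
                met = parts[1]
            else:
                raise NetworkParseError(f"{where}: cannot parse term {term.strip()!r}")
            if met not in known:
                raise NetworkParseError(f"{where}: unknown metabolite {met!r}")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef
    return coeffs, reversible


def parse_network(reactions_file: str | Path, metabolites_file: str | Path) -> StoichiometricNetwork:
    """Parse a network from the two-sheet plain-text definition.

    ``metabolites_file`` is a TSV with columns
    ``metabolite_id, name, role, measurable, etc_member``;
    ``reactions_file`` a TSV with ``reaction_id, pathway, reversible, equation``
    where the equation uses ``A + 2 B -> C`` / ``A <-> B`` syntax.
    The ``reversible`` column must agree with the arrow used.
    """
    mdf = pd.read_csv(metabolites_file, sep="\t", dtype=str)
    required = {"metabolite_id", "name", "role", "measurable", "etc_member"}
    if not required <= set(mdf.columns):
        raise NetworkParseError(f"metabolite sheet lacks columns {sorted(required - set(mdf.columns))}")
    metabolites = [
        Metabolite(
            id=row.metabolite_id,
            name=row.name_ if hasattr(row, "name_") else row.name,
            role=row.role,
            measurable=bool(int(row.measurable)),
            etc_member=bool(int(row.etc_member)),
        )
        for row in mdf.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    known = {m.id for m in metabolites}

    rdf = pd.read_csv(reactions_file, sep="\t", dtype=str)
    required = {"reaction_id", "pathway", "reversible", "equation"}
    if not required <= set(rdf.columns):
        raise NetworkParseError(f"reaction sheet lacks columns {sorted(required - set(rdf.columns))}")
    reactions = []
    for lineno, row in enumerate(rdf.itertuples(index=False), start=2):
        where = f"{reactions_file}:{lineno} ({row.reaction_id})"
        coeffs, rev_from_arrow = _parse_equation(row.equation, known, where)
        declared = bool(int(row.reversible))
        if declared != rev_from_arrow:
            raise NetworkParseError(f"{where}: reversible flag disagrees with arrow")
        reactions.append(
            Reaction(id=row.reaction_id, pathway=row.pathway,
                     reversible=rev_from_arrow, stoichiometry=coeffs)
        )
    return StoichiometricNetwork(metabolites, reactions)


def write_network(net: StoichiometricNetwork, reactions_file: str | Path,
                  metabolites_file: str | Path) -> None:
    """Serialize a network back to the two-sheet TSV definition (round-trips
    with :func:`parse_network`)."""
    mrows = [
        {"metabolite_id": m.id, "name": m.name, "role": m.role,
         "measurable": int(m.measurable), "etc_member": int(m.etc_member)}
        for m in net.metabolites
    ]
    pd.DataFrame(mrows).to_csv(metabolites_file, sep="\t", index=False)

    def fmt(coef: float) -> str:
        return "" if coef == 1.0 else f"{coef:.12g} "

    rrows = []
    for r in net.reactions:
        lhs = " + ".join(f"{fmt(-c)}{m}" for m, c in r.stoichiometry.items() if c < 0)
        rhs = " + ".join(f"{fmt(c)}{m}" for m, c in r.stoichiometry.items() if c > 0)
        arrow = "<->" if r.reversible else "->"
        eq = f"{lhs} {arrow} {rhs}".strip()
        if not lhs:  # pure-production column (e.g. an exchange written as -> A)
            eq = f"{arrow} {rhs}"
        if not rhs:  # pure-consumption column (synthesis)
            eq = f"{lhs} {arrow}"
        rrows.append({"reaction_id": r.id, "pathway": r.pathway,
                      "reversible": int(r.reversible), "equation": eq})
    pd.DataFrame(rrows).to_csv(reactions_file, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("chondroflux").joinpath("data", name)))


def build_full_network() -> StoichiometricNetwork:
    """Load the packaged full network of central energy metabolism
    (52 metabolites x 38 reactions)."""
    net = parse_network(_data_path("reactions.tsv"), _data_path("metabolites.tsv"))
    nm, nr = len(net.metabolites), len(net.reactions)
    if (nm, nr) != (52, 38):  # packaged file corrupt or mis-edited
        raise RuntimeError(f"packaged network has unexpected shape {nm}x{nr}")
    return net


def packaged_measured_ids() -> set[str]:
    """Metabolite ids flagged measurable in the packaged network."""
    return {m.id for m in build_full_network().metabolites if m.measurable}


def reduce_to_measured(net: StoichiometricNetwork, measured_ids: Iterable[str]) -> StoichiometricNetwork:
    """Adapt the full network to a measured-metabolite panel.

    Rules:

    * unmeasured **external** metabolites (e.g. glucose, dissolved gases) are
      removed — their accumulation can neither be observed nor reasonably
      constrained;
    * unmeasured **internal** metabolites are retained with their accumulation
      constrained to zero, preserving pathway connectivity;
    * ETC redox carriers and gradient protons are retained, constrained to
      zero, and additionally flagged for the lowest residual weight;
    * all reaction columns are retained (they merely lose the removed rows).
    """
    measured = set(measured_ids)
    if not measured:
        raise ValueError("measured set is empty")
    known = set(net.metabolite_ids)
    missing = measured - known
    if missing:
        raise ValueError(f"measured ids absent from network: {sorted(missing)}")

    kept: list[Metabolite] = []
    for m in net.metabolites:
        if m.id in measured:
            kept.append(replace(m, measurable=True, constrained_zero=False, lowest_weight=False))
        elif m.role == "external":
            continue  # dropped
        else:
            kept.append(replace(m, measurable=False, constrained_zero=True,
                                lowest_weight=m.etc_member))
    kept_ids = {m.id for m in kept}
    reactions = [
        Reaction(id=r.id, pathway=r.pathway, reversible=r.reversible,
                 stoichiometry={k: v for k, v in r.stoichiometry.items() if k in kept_ids})
        for r in net.reactions
    ]
    return StoichiometricNetwork(kept, reactions)


# ---------------------------------------------------------------------------
# synthesis reactions


def synthesis_from_sequence(
    seq: str,
    product_name: str,
    mapping: Mapping[str, Mapping[str, float]] | None = None,
    normalization: str = "fraction-of-total",
) -> SynthesisReaction:
    """Precursor demand of a protein from its amino-acid sequence.

    Each residue contributes the precursor shares of its biosynthetic family
    (see :data:`RESIDUE_PRECURSORS`); residues whose carbon skeleton does not
    originate in {3PG, PYR, AKG, OAA} contribute nothing and are counted in
    ``skipped_residues``.  Under ``fraction-of-total`` the tallies are
    normalized to sum to one; ``per-molecule`` keeps raw residue counts.
    """
    if not seq:
        raise ValueError("empty sequence")
    if normalization not in ("fraction-of-total", "per-molecule"):
        raise ValueError(f"unknown normalization {normalization!r}")
    table = mapping if mapping is not None else RESIDUE_PRECURSORS
    counts = {p: 0.0 for p in PROTEIN_PRECURSORS}
    skipped = 0
    for pos, res in enumerate(seq.upper()):
        if res not in table:
            raise ValueError(f"unknown residue {res!r} at position {pos}")
        shares = table[res]
        if not shares:
            skipped += 1
            continue
        for prec, share in shares.items():
            if prec not in counts:
                raise ValueError(f"mapping assigns {res!r} outside protein precursors: {prec!r}")
            counts[prec] += share
    counts = {p: c for p, c in counts.items() if c > 0}
    if not counts:
        raise ValueError("sequence contains no residues with central-metabolic precursors")
    if normalization == "fraction-of-total":
        total = sum(counts.values())
        counts = {p: c / total for p, c in counts.items()}
    return SynthesisReaction(product_name=product_name, coefficients=counts,
                             normalization=normalization, skipped_residues=skipped)


def lipid_synthesis_reaction() -> SynthesisReaction:
    """Lipid synthesis draws exclusively on acetyl-CoA."""
    return SynthesisReaction(product_name="lipid", coefficients={"ACCOA": 1.0})


def add_synthesis_reaction(net: StoichiometricNetwork, syn: SynthesisReaction,
                           reaction_id: str | None = None) -> StoichiometricNetwork:
    """Append one irreversible synthesis column: negative coefficients at the
    precursor rows, zero elsewhere (the product lies outside the network)."""
    missing = set(syn.coefficients) - set(net.metabolite_ids)
    if missing:
        raise ValueError(
            f"precursors {sorted(missing)} absent from network; keep precursor "
            "metabolites in the measured set when reducing"
        )
    rid = reaction_id or f"SYN_{re.sub(r'[^A-Za-z0-9]+', '_', syn.product_name)}"
    column = Reaction(id=rid, pathway="SYN", reversible=False,
                      stoichiometry={m: -c for m, c in syn.coefficients.items()})
    return StoichiometricNetwork(list(net.metabolites), list(net.reactions) + [column])
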