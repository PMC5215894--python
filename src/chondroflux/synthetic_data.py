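"""Synthetic replicate intensity tables with known ground-truth fluxes.

The generator emulates the study design this pipeline targets: two
experimental groups (control, compressed), sampling times 0/15/30 min, 4-5
replicates per cell, and metabolite baselines spanning several intensity
decades (lognormal across metabolites).  Given a feasible true flux vector v,
the noiseless cell center of metabolite i at time t is

    center_i(t) = baseline_i + (S v)_i * t

so the accumulation estimator recovers S v exactly at zero noise, and the
whole pipeline can be validated end-to-end.  Replicate noise is
multiplicative (LC-MS intensity noise scales with signal):
``replicate = center * (1 + eps)``, ``eps ~ N(0, noise_cv)``.

What this generator does *not* emulate: chromatographic drift, batch effects,
missingness, and detector saturation.  Passing recovery tests on these tables
therefore demonstrates correctness of the estimation machinery under the
stated noise model, not robustness to real-world acquisition artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .accumulation import IntensityTable
from .exemplar import max_synthesis_profile
from .network import (
    StoichiometricNetwork,
    add_synthesis_reaction,
    build_full_network,
    lipid_synthesis_reaction,
    packaged_measured_ids,
    reduce_to_measured,
    synthesis_from_sequence,
    write_network,
)

__all__ = [
    "SimulationConfig",
    "recovery_experiment",
    "ensemble_correlation_by_noise",
    "generate_true_flux",
    "generate_table",
    "fixture_suite",
    "default_reduced_network",
]


def default_reduced_network(product: str = "collagen2") -> StoichiometricNetwork:
    """Packaged full network reduced to its measurable panel, with one
    protein (or lipid) synthesis column appended — the standard 48 x 39
    analysis matrix."""
    from .io import read_fasta, packaged_protein_fasta

    net = reduce_to_measured(build_full_network(), packaged_measured_ids())
    if product == "lipid":
        syn = lipid_synthesis_reaction()
    else:
        seqs = read_fasta(packaged_protein_fasta())
        key = f"{product}_synthetic"
        if key not in seqs:
            raise ValueError(f"unknown packaged product {product!r}")
        syn = synthesis_from_sequence(seqs[key], product)
    return add_synthesis_reaction(net, syn, reaction_id="SYN")


def generate_true_flux(net: StoichiometricNetwork, mode: str = "protein_like",
                       seed: int = 0) -> np.ndarray:
    """A feasible unit-scale flux vector.

    ``protein_like`` / ``lipid_like`` return the corresponding exemplar LP
    solution (the packaged network must carry a SYN column); ``random`` draws
    a random LP vertex: a uniform random objective optimized subject to the
    zero-accumulation rows, irreversibility, and the unit cap, so the result
    is always consistent with the constraints the solver will assume.
    """
    if mode in ("protein_like", "lipid_like"):
        syn_ids = [r.id for r in net.reactions if r.pathway == "SYN"]
        if not syn_ids:
            raise ValueError(f"mode {mode!r} needs a SYN column in the network")
        if mode == "lipid_like":
            lipid = [r.id for r in net.reactions
                     if r.pathway == "SYN" and set(r.stoichiometry) == {"ACCOA"}]
            if lipid:
                return max_synthesis_profile(net, lipid[0]).v
            # replace the protein column with a lipid one
            base = StoichiometricNetwork(
                list(net.metabolites),
                [r for r in net.reactions if r.pathway != "SYN"])
            net2 = add_synthesis_reaction(base, lipid_synthesis_reaction(), reaction_id="SYN")
            return max_synthesis_profile(net2, "SYN").v
        return max_synthesis_profile(net, syn_ids[0]).v
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r}")

    from scipy.optimize import linprog

    rng = np.random.default_rng(seed)
    zero_rows = np.array([m.constrained_zero for m in net.metabolites])
    if not zero_rows.any():
        zero_rows = np.array([m.role == "internal" and not m.measurable
                              for m in net.metabolites])
    S0 = net.S[zero_rows]
    c = rng.uniform(-1, 1, size=len(net.reactions))
    bounds = [(0.0 if irr else -1.0, 1.0) for irr in net.irreversible_mask]
    res = linprog(c, A_eq=S0 if S0.size else None,
                  b_eq=np.zeros(S0.shape[0]) if S0.size else None,
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"random flux LP failed: {res.message}")
    return res.x


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated experiment.

    ``true_flux`` may be a single per-reaction vector (shared by all groups),
    or a mapping ``group -> vector``, or ``group -> [vector per interval]``
    for piecewise-constant flux between consecutive times.  ``flux_scale``
    rescales the unit-scale vector to intensity/min; the default (None) picks
    the scale automatically so the largest cumulative drawdown uses 25% of
    that metabolite's baseline — positive centers for any seed, with
    realistic 10-30% intensity changes over the full time course.
    """

    network: StoichiometricNetwork
    true_flux: object
    times: tuple[float, ...] = (0.0, 15.0, 30.0)
    groups: tuple[str, ...] = ("control", "compressed")
    n_replicates: int = 5
    baseline_log_mean: float = float(np.log(1e4))
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.05
    flux_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for variance estimation")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if len(self.times) < 2 or list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be an increasing sequence")

    def flux_for(self, group: str, interval_index: int) -> np.ndarray:
        tf = self.true_flux
        if isinstance(tf, dict):
            tf = tf[group]
        tf = np.asarray(tf, dtype=float)
        if tf.ndim == 2:
            return tf[interval_index]
        return tf


def _cumulative_offsets(cfg: SimulationConfig, S: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-scale cumulative center offsets per group: (n_times, n_metabolites)."""
    out = {}
    for g in cfg.groups:
        offs = [np.zeros(S.shape[0])]
        for k in range(len(cfg.times) - 1):
            dt = cfg.times[k + 1] - cfg.times[k]
            v = cfg.flux_for(g, k)
            if np.any(v[np.asarray(cfg.network.irreversible_mask)] < -1e-9):
                raise ValueError("true flux violates irreversibility")
            offs.append(offs[-1] + (S @ v) * dt)
        out[g] = np.vstack(offs)
    return out


def generate_table(cfg: SimulationConfig) -> tuple[IntensityTable, dict]:
    """Simulate a replicate intensity table plus its ground-truth record.

    Only measurable metabolites of the network appear in the table (the
    unmeasured rows have no LC-MS readout by definition).  The ground truth
    contains the scaled flux per group/interval and the exact accumulation
    rates ``S v`` it implies.
    """
    net = cfg.network
    S = net.S
    rng = np.random.default_rng(cfg.seed)
    n_m = len(net.metabolites)
    baselines = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_m))

    offsets = _cumulative_offsets(cfg, S)
    if cfg.flux_scale is None:
        worst = 0.0
        for g in cfg.groups:
            drop = np.maximum(0.0, -offsets[g])  # positive where centers fall
            with np.errstate(divide="ignore"):
                ratios = drop / baselines[None, :]
            worst = max(worst, float(ratios.max()))
        scale = 0.25 / worst if worst > 0 else 1.0
    else:
        scale = float(cfg.flux_scale)

    measurable = [i for i, m in enumerate(net.metabolites) if m.measurable]
    records = []
    for g in cfg.groups:
        for ti, t in enumerate(cfg.times):
            centers = baselines + scale * offsets[g][ti]
            bad = [net.metabolites[i].id for i in measurable if centers[i] <= 0]
            if bad:
                raise ValueError(
                    f"nonpositive centers for {bad}: reduce flux_scale or raise baselines")
            for rep in range(cfg.n_replicates):
                eps = rng.normal(0.0, cfg.noise_cv, size=n_m) if cfg.noise_cv > 0 else np.zeros(n_m)
                values = centers * (1.0 + eps)
                sid = f"{g}_t{t:g}_r{rep + 1}"
                for i in measurable:
                    records.append({"sample_id": sid, "group": g, "time_min": t,
                                    "metabolite_id": net.metabolites[i].id,
                                    "intensity": max(values[i], 1e-9)})
    table = IntensityTable(pd.DataFrame.from_records(records))

    truth = {
        "seed": cfg.seed,
        "flux_scale": scale,
        "noise_cv": cfg.noise_cv,
        "reaction_ids": net.reaction_ids,
        "metabolite_ids": net.metabolite_ids,
        "baselines": baselines.tolist(),
        "true_flux": {
            g: [(scale * cfg.flux_for(g, k)).tolist() for k in range(len(cfg.times) - 1)]
            for g in cfg.groups
        },
        "true_delta": {
            g: [(S @ (scale * cfg.flux_for(g, k))).tolist() for k in range(len(cfg.times) - 1)]
            for g in cfg.groups
        },
    }
    return table, truth


def recovery_experiment(n_runs: int = 100, noise_cv: float = 0.05,
                        n_replicates: int = 5, seed0: int = 0,
                        product: str = "collagen2",
                        interval: tuple[float, float] = (0.0, 15.0)) -> np.ndarray:
    """Estimate-vs-truth Pearson correlations across seeded simulations.

    For each seed: simulate a replicate table from the protein-like ground
    truth, run the standard accumulation -> weights -> BVLS pipeline on the
    compressed group over ``interval``, and correlate the estimated flux
    vector with the generating one.  Returns the per-seed correlations.
    """
    from .accumulation import compute_weights, estimate_accumulation
    from .flux_solver import assemble_problem, solve_flux

    net = default_reduced_network(product)
    v_unit = generate_true_flux(net, "protein_like")
    corrs = []
    for seed in range(seed0, seed0 + n_runs):
        cfg = SimulationConfig(network=net, true_flux=v_unit, noise_cv=noise_cv,
                               n_replicates=n_replicates, seed=seed)
        table, truth = generate_table(cfg)
        acc = compute_weights(estimate_accumulation(
            table, net, "compressed", *interval))
        prof = solve_flux(assemble_problem(net, acc))
        v_true = np.array(truth["true_flux"]["compressed"][0])
        corrs.append(float(np.corrcoef(prof.v, v_true)[0, 1]))
    return np.array(corrs)


def ensemble_correlation_by_noise(cvs=(0.0, 0.02, 0.05, 0.1, 0.2),
                                  n_seeds: int = 5, n_sets: int = 8,
                                  seed0: int = 0,
                                  product: str = "collagen2") -> list[float]:
    """Median randomization-ensemble correlation at each generator noise
    level (median over seeds of the per-run median).  Used to check that
    ensemble agreement never improves as the data get noisier."""
    from .sensitivity import sensitivity_run

    net = default_reduced_network(product)
    v_unit = generate_true_flux(net, "protein_like")
    medians = []
    for cv in cvs:
        per_seed = []
        for seed in range(seed0, seed0 + n_seeds):
            cfg = SimulationConfig(network=net, true_flux=v_unit, noise_cv=cv,
                                   seed=seed)
            table, _ = generate_table(cfg)
            res = sensitivity_run(table, net, [(0, 15)], n_sets=n_sets,
                                  seed=seed + 1000)
            per_seed.append(float(np.median(res.correlations[(0.0, 15.0)])))
        medians.append(float(np.median(per_seed)))
    return medians


def fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the package's small versioned fixtures to ``outdir``.

    Regeneration with the same seed is byte-identical.  Includes a
    3-metabolite toy network, a 6-sample clustering table, a small solver
    instance with its recorded optimum, and the packaged full and reduced
    (with collagen-II synthesis) network sheets.
    """
    from .io import write_intensity_csv
    from .network import Metabolite, Reaction

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = StoichiometricNetwork(
        [Metabolite("A", role="external"), Metabolite("B"),
         Metabolite("C", role="external")],
        [Reaction("R1", "G", False, {"A": -1, "B": 1}),
         Reaction("R2", "G", True, {"B": -1, "C": 1})],
    )
    paths["toy_reactions"] = outdir / "toy_reactions.tsv"
    paths["toy_metabolites"] = outdir / "toy_metabolites.tsv"
    write_network(toy, paths["toy_reactions"], paths["toy_metabolites"])

    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(4)]
    records = []
    for s in range(6):
        base = rng.uniform(50, 150, size=len(mets))
        for m, val in zip(mets, base):
            records.append({"sample_id": f"S{s}", "group": "control",
                            "time_min": 0.0, "metabolite_id": m, "intensity": val})
    paths["cluster_table"] = outdir / "cluster_table.csv"
    write_intensity_csv(IntensityTable(pd.DataFrame(records)), paths["cluster_table"])

    A = rng.normal(size=(6, 4))
    b = rng.normal(size=6)
    lb = np.array([0.0, 0.0, -np.inf, -np.inf])
    from .flux_solver import FluxBVLS
    est = FluxBVLS(lower_bounds=lb).fit(A, b)
    inst = {"A": A.tolist(), "b": b.tolist(), "lower_bounds": [0, 0, None, None],
            "objective": est.objective_, "x": est.flux_.tolist()}
    paths["solver_instance"] = outdir / "solver_instance.json"
    paths["solver_instance"].write_text(json.dumps(inst, indent=1, sort_keys=True))

    full = build_full_network()
    paths["full_reactions"] = outdir / "full_reactions.tsv"
    paths["full_metabolites"] = outdir / "full_metabolites.tsv"
    write_network(full, paths["full_reactions"], paths["full_metabolites"])
    reduced = default_reduced_network("collagen2")
    paths["reduced_reactions"] = outdir / "reduced_reactions.tsv"
    paths["reduced_metabolites"] = outdir / "reduced_metabolites.tsv"
    write_network(reduced, paths["reduced_reactions"], paths["reduced_metabolites"])
    return paths
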