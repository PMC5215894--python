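"""End-to-end orchestration: accumulation -> weights -> flux per interval ->
exemplar comparison -> sensitivity -> sample clustering, with a JSON manifest
recording seeds, settings and output checksums."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import io as cfio
from .accumulation import anova_screen, compute_weights, estimate_accumulation
from .exemplar import compare_profiles, max_synthesis_profile, profile_shape_features
from .flux_solver import assemble_problem, residual_report, solve_flux
from .network import (build_full_network, packaged_measured_ids, parse_network,
                      reduce_to_measured)
from .sensitivity import cluster_samples, flux_metabolite_correlation, sensitivity_run
from .synthetic_data import default_reduced_network

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    table_path: str
    out_dir: str
    network_reactions: str | None = None   # None -> packaged network
    network_metabolites: str | None = None
    product: str = "collagen2"
    intervals: tuple[tuple[float, float], ...] = ((0.0, 15.0), (15.0, 30.0), (0.0, 30.0))
    group: str = "compressed"
    center: str = "median"
    hard_zero: bool = False
    anova_alpha: float = 0.15
    n_sets: int = 200
    seed: int = 17
    linkage: str = "average"

    def validate(self) -> None:
        if not Path(self.table_path).exists():
            raise FileNotFoundError(f"intensity table not found: {self.table_path}")
        for p in (self.network_reactions, self.network_metabolites):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"network file not found: {p}")
        if (self.network_reactions is None) != (self.network_metabolites is None):
            raise ValueError("provide both network sheets or neither")


def _load_network(cfg: RunConfig):
    if cfg.network_reactions is None:
        return default_reduced_network(cfg.product)
    net = parse_network(cfg.network_reactions, cfg.network_metabolites)
    if any(r.pathway == "SYN" for r in net.reactions):
        return net
    measured = {m.id for m in net.metabolites if m.measurable}
    return reduce_to_measured(net, measured)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write a deterministic output directory.

    Returns the manifest dict (also written as ``manifest.json``)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = _load_network(cfg)
    table = cfio.read_intensity_csv(cfg.table_path)

    outputs: dict[str, Path] = {}

    # 1. ANOVA screen
    screen = anova_screen(table, alpha=cfg.anova_alpha)
    screen_path = out / "anova_screen.csv"
    screen.to_csv(screen_path, float_format="%.12g")
    outputs["anova_screen"] = screen_path

    # 2. accumulation + flux per interval
    fluxes = {}
    for (t0, t1) in cfg.intervals:
        acc = compute_weights(estimate_accumulation(table, net, cfg.group, t0, t1,
                                                    center=cfg.center))
        prob = assemble_problem(net, acc, hard_zero=cfg.hard_zero)
        prof = solve_flux(prob)
        fluxes[(t0, t1)] = prof
        tag = f"{t0:g}_{t1:g}"
        cfio.write_accumulation_csv(acc, out / f"accumulation_{tag}.csv")
        cfio.write_flux_csv(prof, net, out / f"flux_{tag}.csv")
        residual_report(prof).to_csv(out / f"residuals_{tag}.csv", float_format="%.12g")
        outputs[f"accumulation_{tag}"] = out / f"accumulation_{tag}.csv"
        outputs[f"flux_{tag}"] = out / f"flux_{tag}.csv"
        outputs[f"residuals_{tag}"] = out / f"residuals_{tag}.csv"

    # 3. exemplar comparison (only when the network carries a SYN column)
    exemplar_stats = {}
    syn_ids = [r.id for r in net.reactions if r.pathway == "SYN"]
    if syn_ids:
        ex = max_synthesis_profile(net, syn_ids[0])
        cfio.write_flux_csv(ex, net, out / "exemplar.csv")
        outputs["exemplar"] = out / "exemplar.csv"
        exemplar_stats["shape_features"] = profile_shape_features(ex, net)
        for iv, prof in fluxes.items():
            if np.linalg.norm(prof.v) > 0 and np.linalg.norm(ex.v) > 0:
                rel, _ = compare_profiles(prof, ex)
                exemplar_stats[f"distance_to_exemplar_{iv[0]:g}_{iv[1]:g}"] = rel

    # 4. sensitivity
    sens = sensitivity_run(table, net, cfg.intervals, n_sets=cfg.n_sets,
                           seed=cfg.seed, group=cfg.group, center=cfg.center,
                           hard_zero=cfg.hard_zero)
    sens_path = out / "sensitivity_summary.csv"
    sens.summary().to_csv(sens_path, index=False, float_format="%.12g")
    outputs["sensitivity_summary"] = sens_path
    for iv in cfg.intervals:
        c = sens.correlations[tuple(map(float, iv))]
        counts, edges = np.histogram(c, bins=40, range=(-1.0, 1.0))
        hist = out / f"correlation_hist_{iv[0]:g}_{iv[1]:g}.csv"
        np.savetxt(hist, np.column_stack([edges[:-1], edges[1:], counts]),
                   delimiter=",", header="bin_lo,bin_hi,count", comments="")
        outputs[f"correlation_hist_{iv[0]:g}_{iv[1]:g}"] = hist

    from .plots import plot_correlation_histogram, plot_heatmap

    iv_first = tuple(map(float, cfg.intervals[0]))
    if len(sens.correlations[iv_first]):
        plot_correlation_histogram(
            sens.correlations[iv_first], out / "correlation_hist.png",
            title=f"interval {iv_first[0]:g}-{iv_first[1]:g} min")
        outputs["correlation_hist_png"] = out / "correlation_hist.png"

    # 5. flux-accumulation correlation clustering on the first interval ensemble
    iv0 = tuple(map(float, cfg.intervals[0]))
    if sens.ensemble[iv0].shape[0] >= 3:
        corr, row_link, col_link, _ = flux_metabolite_correlation(
            sens.ensemble[iv0], sens.accumulation_ensemble[iv0],
            reaction_ids=net.reaction_ids, metabolite_ids=net.metabolite_ids,
            linkage_method=cfg.linkage)
        corr_path = out / "flux_metabolite_correlation.csv"
        corr.to_csv(corr_path, float_format="%.12g")
        outputs["flux_metabolite_correlation"] = corr_path
        plot_heatmap(corr, out / "flux_metabolite_correlation.png",
                     title="flux vs accumulation correlation")
        outputs["flux_metabolite_correlation_png"] = out / "flux_metabolite_correlation.png"
        (out / "flux_dendrogram.nwk").write_text(
            cfio.linkage_to_newick(row_link, net.reaction_ids) + "\n")
        outputs["flux_dendrogram"] = out / "flux_dendrogram.nwk"

    # 6. sample clustering on the ANOVA-flagged subset (fall back to all)
    flagged = list(screen.index[screen["flagged"]])
    subset = flagged if flagged else list(screen.index)
    clust = cluster_samples(table, subset, linkage_method=cfg.linkage)
    clust["distance"].to_csv(out / "sample_distance.csv", float_format="%.12g")
    clust["standardized"].to_csv(out / "sample_heatmap.csv", float_format="%.12g")
    plot_heatmap(clust["standardized"][clust["order"]], out / "sample_heatmap.png",
                 title="standardized intensities (samples in cluster order)")
    outputs["sample_heatmap_png"] = out / "sample_heatmap.png"
    (out / "sample_dendrogram.nwk").write_text(
        cfio.linkage_to_newick(clust["linkage"], clust["samples"]) + "\n")
    outputs["sample_distance"] = out / "sample_distance.csv"
    outputs["sample_heatmap"] = out / "sample_heatmap.csv"
    outputs["sample_dendrogram"] = out / "sample_dendrogram.nwk"

    manifest = {
        "config": asdict(cfg),
        "network": {"n_metabolites": len(net.metabolites),
                    "n_reactions": len(net.reactions)},
        "anova_flagged": flagged,
        "exemplar": exemplar_stats,
        "sensitivity": {"n_failed": sens.n_failed, "seed": cfg.seed,
                        "n_sets": cfg.n_sets},
        "flux_objectives": {f"{iv[0]:g}_{iv[1]:g}": fluxes[iv].objective
                            for iv in fluxes},
        "outputs": outputs,
    }
    return cfio.write_manifest(out / "manifest.json", manifest)
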