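"""Randomization-based robustness analysis and correlation clustering.

How stable are the inferred fluxes against replicate-level measurement
noise?  Each randomized data set replaces every (group, time, metabolite)
cell with draws from a normal distribution centered at the cell mean,
scaled by the standard error, and truncated to the 95% confidence interval
of the mean.  Re-running the full accumulation -> weighting -> BVLS pipeline
on each randomized set and correlating the resulting flux vector with the
original yields a correlation histogram per interval; a mass of correlations
above 0.5 indicates a robust flux estimate.

The module also provides the two clustering views used to explore the data:
pairwise flux-accumulation correlation across the randomized ensemble
(hierarchically clustered with Euclidean distance), and sample clustering
with correlation distance (1 - Pearson r) on column-standardized
intensities, exposed as a scikit-learn-style estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .accumulation import IntensityTable, compute_weights, estimate_accumulation
from .flux_solver import assemble_problem, solve_flux
from .network import StoichiometricNetwork

__all__ = [
    "SensitivityResult",
    "randomize_table",
    "sensitivity_run",
    "flux_metabolite_correlation",
    "CorrelationCluster",
    "cluster_samples",
]


@dataclass
class SensitivityResult:
    n_sets: int
    seed: int
    intervals: list[tuple[float, float]]
    #: interval -> per-set Pearson correlation with the original flux vector
    correlations: dict[tuple[float, float], np.ndarray]
    #: interval -> fraction of sets with correlation > 0.5
    fraction_above: dict[tuple[float, float], float]
    #: interval -> (n_kept_sets, n_reactions) randomized flux vectors
    ensemble: dict[tuple[float, float], np.ndarray]
    #: interval -> (n_kept_sets, n_metabolites) randomized accumulation rates
    accumulation_ensemble: dict[tuple[float, float], np.ndarray]
    original_flux: dict[tuple[float, float], np.ndarray]
    n_failed: int = 0
    reaction_ids: list[str] | None = None
    metabolite_ids: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            c = self.correlations[iv]
            rows.append({"t0": iv[0], "t1": iv[1], "n_sets": len(c),
                         "median_correlation": float(np.median(c)),
                         "fraction_above_0.5": self.fraction_above[iv]})
        return pd.DataFrame(rows)


def randomize_table(table: IntensityTable, n_sets: int, seed: int) -> Iterator[IntensityTable]:
    """Stream of randomized intensity tables.

    Per (group, time, metabolite) cell: compute the replicate mean m and the
    standard error of the mean; replacement replicates are drawn
    independently from N(m, SE) truncated (by counted rejection) to the 95%
    confidence interval m +/- 1.96 SE.  A cell with zero variance reproduces
    m exactly.  Deterministic given the seed.
    """
    d = table.data
    counts = d.groupby(["group", "time_min", "metabolite_id"])["intensity"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with a single replicate cannot be randomized: {bad[:5]}")
    stats = d.groupby(["group", "time_min", "metabolite_id"])["intensity"].agg(["mean", "std", "count"])
    sd = stats["std"].to_numpy()
    mean = stats["mean"].to_numpy()
    # identical replicates can carry a floating-point-noise variance; such a
    # cell has a point confidence interval and must reproduce its data exactly
    sd = np.where(sd < 1e-10 * np.maximum(np.abs(mean), 1e-300), 0.0, sd)
    se = sd / np.sqrt(stats["count"].to_numpy())
    key = pd.MultiIndex.from_frame(d[["group", "time_min", "metabolite_id"]])
    pos = {k: i for i, k in enumerate(stats.index)}
    row_cell = np.array([pos[k] for k in key])
    original = d["intensity"].to_numpy()
    degenerate = se[row_cell] == 0

    rng = np.random.default_rng(seed)
    lo, hi = mean - 1.96 * se, mean + 1.96 * se
    for _ in range(n_sets):
        vals = rng.normal(mean[row_cell], se[row_cell])
        out_of_ci = (vals < lo[row_cell]) | (vals > hi[row_cell])
        # counted rejection: redraw only the out-of-interval entries
        while out_of_ci.any():
            idx = np.flatnonzero(out_of_ci)
            vals[idx] = rng.normal(mean[row_cell[idx]], se[row_cell[idx]])
            out_of_ci = np.zeros_like(out_of_ci)
            out_of_ci[idx] = (vals[idx] < lo[row_cell[idx]]) | (vals[idx] > hi[row_cell[idx]])
        vals = np.where(degenerate, original, vals)
        new = d.copy()
        new["intensity"] = np.maximum(vals, 0.0)
        yield IntensityTable(new)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    if np.array_equal(a, b):
        return 1.0  # exact by definition; corrcoef would add float noise
    return float(np.corrcoef(a, b)[0, 1])


def _pipeline_fluxes(table, net, group, intervals, center, hard_zero):
    out = {}
    acc_out = {}
    for (t0, t1) in intervals:
        acc = compute_weights(estimate_accumulation(table, net, group, t0, t1, center=center),
                              on_degenerate="unit")
        prob = assemble_problem(net, acc, hard_zero=hard_zero)
        out[(t0, t1)] = solve_flux(prob).v
        acc_out[(t0, t1)] = acc.delta
    return out, acc_out


def sensitivity_run(
    table: IntensityTable,
    net: StoichiometricNetwork,
    intervals: Sequence[tuple[float, float]],
    n_sets: int,
    seed: int,
    group: str = "compressed",
    center: str = "median",
    hard_zero: bool = False,
) -> SensitivityResult:
    """Full randomization study: per randomized set and interval, recompute
    accumulations, weights and fluxes with identical settings, and correlate
    each randomized flux vector with the original one."""
    intervals = [tuple(map(float, iv)) for iv in intervals]
    original, _ = _pipeline_fluxes(table, net, group, intervals, center, hard_zero)

    corr = {iv: [] for iv in intervals}
    ens = {iv: [] for iv in intervals}
    acc_ens = {iv: [] for iv in intervals}
    n_failed = 0
    for rnd in randomize_table(table, n_sets, seed):
        try:
            fluxes, accs = _pipeline_fluxes(rnd, net, group, intervals, center, hard_zero)
        except (RuntimeError, ValueError):
            n_failed += 1  # counted, never silently dropped
            continue
        for iv in intervals:
            corr[iv].append(_pearson(fluxes[iv], original[iv]))
            ens[iv].append(fluxes[iv])
            acc_ens[iv].append(accs[iv])

    correlations = {iv: np.array(corr[iv]) for iv in intervals}
    return SensitivityResult(
        n_sets=n_sets, seed=seed, intervals=intervals,
        correlations=correlations,
        fraction_above={iv: float(np.mean(c > 0.5)) if len(c) else 0.0
                        for iv, c in correlations.items()},
        ensemble={iv: np.array(ens[iv]) for iv in intervals},
        accumulation_ensemble={iv: np.array(acc_ens[iv]) for iv in intervals},
        original_flux=original, n_failed=n_failed,
        reaction_ids=net.reaction_ids, metabolite_ids=net.metabolite_ids,
    )


def flux_metabolite_correlation(
    flux_ensemble: np.ndarray,
    accumulation_ensemble: np.ndarray,
    reaction_ids: Sequence[str] | None = None,
    metabolite_ids: Sequence[str] | None = None,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Reactions x metabolites Pearson correlation across an ensemble,
    with hierarchical row/column clustering (Euclidean distance).

    Entries where the flux or accumulation is constant across the ensemble
    are undefined and reported as 0 with a flag.  Returns
    (correlation frame, row linkage, column linkage, undefined-flag frame).
    """
    F = np.asarray(flux_ensemble, float)     # (n_sets, n_reactions)
    A = np.asarray(accumulation_ensemble, float)  # (n_sets, n_metabolites)
    if F.shape[0] != A.shape[0]:
        raise ValueError("ensembles have different sizes")
    if F.shape[0] < 3:
        raise ValueError("need an ensemble of at least 3 sets")
    Fc = F - F.mean(axis=0)
    Ac = A - A.mean(axis=0)
    sf, sa = Fc.std(axis=0), Ac.std(axis=0)
    C = (Fc.T @ Ac) / F.shape[0]
    denom = np.outer(sf, sa)
    undefined = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(undefined, 0.0, C / np.where(denom == 0, 1.0, denom))
    C = np.clip(C, -1.0, 1.0)
    ridx = list(reaction_ids) if reaction_ids is not None else list(range(F.shape[1]))
    cidx = list(metabolite_ids) if metabolite_ids is not None else list(range(A.shape[1]))
    frame = pd.DataFrame(C, index=ridx, columns=cidx)
    row_link = hierarchy.linkage(C, method=linkage_method, metric="euclidean")
    col_link = hierarchy.linkage(C.T, method=linkage_method, metric="euclidean")
    flags = pd.DataFrame(undefined, index=ridx, columns=cidx)
    return frame, row_link, col_link, flags


class CorrelationCluster(ClusterMixin, BaseEstimator):
    """Agglomerative sample clustering with correlation distance.

    Columns (samples) are z-standardized; the pairwise distance between two
    samples is ``1 - Pearson r`` of their standardized intensity profiles.

    Attributes (after fit): ``distance_``, ``linkage_``, ``leaf_order_``,
    ``labels_`` (two flat clusters, matching the two-block structure these
    heatmaps are read for), ``standardized_`` (metabolites x samples).
    """

    def __init__(self, linkage_method: str = "average", n_clusters: int = 2):
        self.linkage_method = linkage_method
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)  # metabolites x samples
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        self.excluded_ = np.flatnonzero(~keep)
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0, ddof=0)
        R = np.corrcoef(Z.T)
        D = np.clip(1.0 - R, 0.0, None)
        np.fill_diagonal(D, 0.0)
        self.distance_ = D
        self.linkage_ = hierarchy.linkage(squareform(D, checks=False),
                                          method=self.linkage_method)
        self.leaf_order_ = hierarchy.leaves_list(self.linkage_)
        self.labels_ = hierarchy.fcluster(self.linkage_, self.n_clusters,
                                          criterion="maxclust") - 1
        self.standardized_ = Z
        return self


def cluster_samples(
    table: IntensityTable,
    metabolite_subset: Sequence[str],
    linkage_method: str = "average",
) -> dict:
    """Cluster samples on a metabolite subset (typically the ANOVA-flagged set).

    Returns sample ordering, the linkage matrix, the pairwise 1 - r distance
    matrix, and the column-standardized heatmap matrix (metabolites x samples).
    """
    subset = list(metabolite_subset)
    if not subset:
        raise ValueError("metabolite subset is empty")
    wide = (table.data[table.data["metabolite_id"].isin(subset)]
            .pivot(index="metabolite_id", columns="sample_id", values="intensity")
            .reindex(subset))
    if wide.isna().any().any():
        raise ValueError("subset metabolites missing for some samples")
    sd = wide.std(axis=0, ddof=0)
    dropped = list(sd[sd == 0].index)
    if dropped:
        import warnings
        warnings.warn(f"samples with zero variance over subset excluded: {dropped}")
        wide = wide.drop(columns=dropped)
    est = CorrelationCluster(linkage_method=linkage_method).fit(wide.to_numpy())
    samples = list(wide.columns)
    return {
        "samples": samples,
        "order": [samples[i] for i in est.leaf_order_],
        "linkage": est.linkage_,
        "distance": pd.DataFrame(est.distance_, index=samples, columns=samples),
        "standardized": pd.DataFrame(est.standardized_, index=wide.index, columns=samples),
        "labels": dict(zip(samples, est.labels_.tolist())),
        "excluded": dropped,
    }
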