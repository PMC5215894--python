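"""Per-metabolite accumulation rates, variances and regression weights.

An intensity table holds replicate LC-MS intensities keyed by
(sample, group, time, metabolite).  For a group and a time interval
``[t0, t1]`` the accumulation rate of metabolite *i* is

    delta_i = (center(a at t1) - center(a at t0)) / (t1 - t0)

with ``center`` either the mean or, for small samples, the median (which
curtails the influence of outliers).  The variance attached to the difference
of two group means with unequal variances is the Welch form
``s1^2/n1 + s2^2/n2``; because the rate divides by the interval length, the
variance carried by delta is that quantity divided by ``(t1 - t0)^2``.  The
regression weight of a metabolite is the reciprocal of its variance, so the
flux fit trusts precisely those accumulations that are reproducible across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import StoichiometricNetwork

__all__ = [
    "IntensityTable",
    "AccumulationVector",
    "estimate_accumulation",
    "estimate_variance",
    "compute_weights",
    "anova_screen",
]

REQUIRED_COLUMNS = ("sample_id", "group", "time_min", "metabolite_id", "intensity")


@dataclass
class IntensityTable:
    """Long-format replicate intensity table with light validation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"intensity table lacks columns {sorted(missing)}")
        df = self.data.copy()
        df["time_min"] = df["time_min"].astype(float)
        df["intensity"] = df["intensity"].astype(float)
        if (df["intensity"] < 0).any():
            raise ValueError("negative intensities")
        dup = df.duplicated(["sample_id", "metabolite_id"])
        if dup.any():
            raise ValueError("duplicate (sample_id, metabolite_id) pairs")
        self.data = df

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.data["time_min"].unique())

    def cell(self, group: str, time: float, metabolite: str) -> np.ndarray:
        d = self.data
        sel = (d["group"] == group) & (d["time_min"] == time) & (d["metabolite_id"] == metabolite)
        return d.loc[sel, "intensity"].to_numpy()

    def apply_floor(self, limit_of_detection: float) -> "IntensityTable":
        """Optional limit-of-detection filter: drop records below the floor."""
        return IntensityTable(self.data[self.data["intensity"] >= limit_of_detection].copy())


@dataclass
class AccumulationVector:
    """Accumulation rates over one interval, aligned to a reduced network."""

    interval: tuple[float, float]
    table: pd.DataFrame  # index metabolite_id; delta, variance, weight, flags
    center: str = "median"

    def __post_init__(self) -> None:
        t0, t1 = self.interval
        if not t1 > t0:
            raise ValueError(f"need t1 > t0, got {self.interval}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def delta(self) -> np.ndarray:
        return self.table["delta"].to_numpy()

    @property
    def variance(self) -> np.ndarray:
        return self.table["variance"].to_numpy()

    @property
    def weight(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    @property
    def constrained_zero(self) -> np.ndarray:
        return self.table["constrained_zero"].to_numpy()

    @property
    def lowest_weight(self) -> np.ndarray:
        return self.table["lowest_weight"].to_numpy()


def _center(values: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.median(values))
    if how == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown center {how!r}")


def _sample_var(values: np.ndarray) -> float:
    """Unbiased sample variance, snapped to exact zero when the spread is at
    floating-point noise level (identical replicates can yield a variance of
    ~(x*eps)^2 instead of 0, which would explode inverse-variance weights)."""
    v = float(np.var(values, ddof=1))
    scale = abs(float(np.mean(values)))
    if v < (1e-10 * max(scale, 1e-300)) ** 2:
        return 0.0
    return v


def estimate_variance(s1_sq: float, n1: int, s2_sq: float, n2: int) -> float:
    """Welch variance of a difference of two sample means: s1^2/n1 + s2^2/n2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per sample for a variance")
    if s1_sq < 0 or s2_sq < 0:
        raise ValueError("sample variances must be nonnegative")
    return s1_sq / n1 + s2_sq / n2


def estimate_accumulation(
    table: IntensityTable,
    net: StoichiometricNetwork,
    group: str,
    t0: float,
    t1: float,
    center: str = "median",
) -> AccumulationVector:
    """Accumulation rates for every network row over ``[t0, t1]``.

    Measurable metabolites take the replicate-center difference divided by the
    interval; constrained-zero rows (unmeasured internal metabolites, ETC
    carriers) get delta = 0 regardless of data.  Variances (Welch, divided by
    the squared interval) are populated here; weights are attached by
    :func:`compute_weights`.
    """
    if t1 <= t0:
        raise ValueError(f"need t1 > t0, got ({t0}, {t1})")
    for t in (t0, t1):
        if t not in table.times:
            raise ValueError(f"time {t} not present in table")
    dt = t1 - t0

    rows = []
    missing: list[str] = []
    for m in net.metabolites:
        if m.constrained_zero or not m.measurable:
            rows.append({"metabolite_id": m.id, "delta": 0.0, "variance": np.nan,
                         "constrained_zero": True,
                         "lowest_weight": m.lowest_weight or m.etc_member})
            continue
        a0 = table.cell(group, t0, m.id)
        a1 = table.cell(group, t1, m.id)
        if len(a0) == 0 or len(a1) == 0:
            missing.append(m.id)
            continue
        if len(a0) < 2 or len(a1) < 2:
            raise ValueError(f"metabolite {m.id!r}: need >=2 replicates per time point")
        delta = (_center(a1, center) - _center(a0, center)) / dt
        var = estimate_variance(_sample_var(a0), len(a0),
                                _sample_var(a1), len(a1)) / dt**2
        rows.append({"metabolite_id": m.id, "delta": delta, "variance": var,
                     "constrained_zero": False, "lowest_weight": False})
    if missing:
        raise ValueError(f"metabolites absent at one or both time points: {missing}")
    df = pd.DataFrame(rows).set_index("metabolite_id")
    df["weight"] = np.nan
    return AccumulationVector(interval=(t0, t1), table=df, center=center)


def compute_weights(acc: AccumulationVector, zero_var_policy: str = "cap",
                    on_degenerate: str = "raise") -> AccumulationVector:
    """Attach inverse-variance weights.

    * measured rows: w = 1/variance;
    * zero-variance rows: by default capped at the largest finite measured
      weight ("cap"); the "epsilon" policy instead floors the variance at
      1e-12 times the largest measured variance;
    * ETC / lowest-weight rows: the minimum over measured weights;
    * remaining constrained-zero rows: left NaN here — the solver assembly
      assigns them the median measured weight (soft constraint) or turns them
      into hard equalities.

    A table where *every* measured variance is zero carries no reliability
    information at all; by default this degenerate case raises, but
    ``on_degenerate="unit"`` assigns uniform unit weights instead (used by the
    sensitivity pipeline, where noise-free input is a legitimate edge case).
    """
    if zero_var_policy not in ("cap", "epsilon"):
        raise ValueError(f"unknown zero_var_policy {zero_var_policy!r}")
    if on_degenerate not in ("raise", "unit"):
        raise ValueError(f"unknown on_degenerate {on_degenerate!r}")
    df = acc.table.copy()
    measured = ~df["constrained_zero"]
    var = df.loc[measured, "variance"]
    if measured.any() and (var == 0).all():
        if on_degenerate == "raise":
            raise ValueError("all measured variances are zero; data degenerate")
        df["weight"] = 1.0
        return AccumulationVector(interval=acc.interval, table=df, center=acc.center)

    pos = var[var > 0]
    w = pd.Series(np.nan, index=df.index)
    w[measured] = 1.0 / var.where(var > 0)
    if zero_var_policy == "cap":
        w[measured & (df["variance"] == 0)] = (1.0 / pos).max()
    else:
        floor = 1e-12 * pos.max()
        w[measured & (df["variance"] == 0)] = 1.0 / floor

    w_measured = w[measured]
    w[df["lowest_weight"]] = w_measured.min()
    df["weight"] = w
    return AccumulationVector(interval=acc.interval, table=df, center=acc.center)


def anova_screen(
    table: IntensityTable,
    alpha: float = 0.15,
    group: str | None = None,
    two_factor: bool = False,
) -> pd.DataFrame:
    """Screen metabolites for a time effect by ANOVA.

    One-factor mode tests the duration factor on one experimental group (or
    on all records pooled when ``group`` is None); two-factor mode fits
    ``intensity ~ C(time) + C(group) + C(time):C(group)`` and reports the time
    main effect.  Returns a frame indexed by metabolite with columns
    ``p_value`` and ``flagged`` (p <= alpha).  Metabolites with no intensity
    variation at all take p = 1 by convention (no evidence of change).
    """
    d = table.data
    if group is not None:
        d = d[d["group"] == group]
    out = []
    for met, sub in d.groupby("metabolite_id"):
        times = sub["time_min"].unique()
        if len(times) < 2:
            continue  # cannot test; excluded
        if np.allclose(sub["intensity"].var(ddof=0), 0.0):
            out.append({"metabolite_id": met, "p_value": 1.0})
            continue
        if two_factor and sub["group"].nunique() > 1:
            import statsmodels.api as sm
            import statsmodels.formula.api as smf

            fit = smf.ols("intensity ~ C(time_min) * C(group)", data=sub).fit()
            tbl = sm.stats.anova_lm(fit, typ=2)
            p = float(tbl.loc["C(time_min)", "PR(>F)"])
        else:
            samples = [g["intensity"].to_numpy() for _, g in sub.groupby("time_min")]
            p = float(stats.f_oneway(*samples).pvalue)
        if np.isnan(p):  # zero between/within variance edge cases
            p = 1.0
        out.append({"metabolite_id": met, "p_value": p})
    res = pd.DataFrame(out).set_index("metabolite_id").sort_index()
    res["flagged"] = res["p_value"] <= alpha
    return res
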