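"""Group-level inference on distance-binned profiles.

The experimental unit is the animal: each row of a :class:`ProfileMatrix` is one
animal's (windowed, normalized) density profile, each column a distance bin. The
primary test is a fixed-effects two-way ANOVA with genotype/group and distance bin
as crossed categorical factors plus their interaction; because distance bins are
repeated measures within an animal, a group-label permutation test on the same F
statistic is provided as a distribution-free companion, and reports print both.
Pointwise two-group comparisons at named distances default to Welch's t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import AnalysisError
from .profiles import DensityProfile

__all__ = [
    "ProfileMatrix",
    "two_way_anova",
    "balanced_anova",
    "permutation_group_test",
    "compare_at_distance",
    "GroupComparison",
]

_RESIDUAL_TOL = 1e-12


@dataclass
class ProfileMatrix:
    """Animals x distance-bins matrix of per-animal profile values."""

    values: np.ndarray                 # (n_animals, n_bins)
    groups: np.ndarray                 # group label per row
    animals: np.ndarray                # animal id per row
    bin_centers: np.ndarray            # um
    window: tuple[float, float] | None = None
    channel: str = ""

    @classmethod
    def from_profiles(cls, profiles: Sequence[DensityProfile], channel: str = "") -> "ProfileMatrix":
        """Stack per-animal profiles (same bin grid required) into a matrix."""
        if not profiles:
            raise AnalysisError("no profiles")
        ref = profiles[0]
        for p in profiles[1:]:
            if p.bin_edges.shape != ref.bin_edges.shape or not np.allclose(p.bin_edges, ref.bin_edges):
                raise AnalysisError("profiles use mixed bin grids")
        return cls(
            values=np.vstack([p.bin_means for p in profiles]),
            groups=np.array([p.group for p in profiles]),
            animals=np.array([p.animal for p in profiles]),
            bin_centers=ref.bin_centers.copy(),
            window=(float(ref.bin_edges[0]), float(ref.bin_edges[-1])),
            channel=channel or ref.channel,
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.values)):
            for j, c in enumerate(self.bin_centers):
                v = self.values[i, j]
                if np.isnan(v):
                    continue
                rows.append(
                    {
                        "value": v,
                        "group": self.groups[i],
                        "animal": self.animals[i],
                        "dist": f"{c:g}",
                    }
                )
        return pd.DataFrame(rows)

    def group_levels(self) -> np.ndarray:
        return np.unique(self.groups)


def _check_design(matrix: ProfileMatrix) -> None:
    levels = matrix.group_levels()
    if len(levels) < 2:
        raise AnalysisError("need >= 2 groups for inference")
    for g in levels:
        if (matrix.groups == g).sum() < 2:
            raise AnalysisError(f"group {g!r} has < 2 animals")
    if matrix.values.shape[1] < 2:
        raise AnalysisError("need >= 2 distance bins")
    for g in levels:
        sub = matrix.values[matrix.groups == g]
        empty = np.flatnonzero(np.all(np.isnan(sub), axis=0))
        if empty.size:
            c = matrix.bin_centers[empty[0]]
            raise AnalysisError(f"cell (group {str(g)!r}, distance {c:g} um) has no observations")


def two_way_anova(matrix: ProfileMatrix) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA: value ~ group * distance-bin (both categorical).

    Returns the table indexed by effect (``group``, ``distance``, ``interaction``,
    ``residual``) with columns ``sum_sq``, ``df``, ``mean_sq``, ``F``, ``p``.
    Balanced designs reproduce the classical SS decomposition exactly; unbalanced
    designs use Type II sums of squares.
    """
    _check_design(matrix)
    long = matrix.to_long()
    model = smf.ols("value ~ C(group) * C(dist)", data=long).fit()
    raw = sm.stats.anova_lm(model, typ=2)
    resid_df = raw.loc["Residual", "df"]
    if resid_df <= 0:
        raise AnalysisError("zero residual degrees of freedom")
    resid_ms = raw.loc["Residual", "sum_sq"] / resid_df
    scale = max(raw["sum_sq"].sum(), 1.0)
    if resid_ms <= _RESIDUAL_TOL * scale:
        raise AnalysisError("residual sum of squares is zero; F statistics undefined")
    rename = {
        "C(group)": "group",
        "C(dist)": "distance",
        "C(group):C(dist)": "interaction",
        "Residual": "residual",
    }
    table = raw.rename(index=rename)[["sum_sq", "df", "F", "PR(>F)"]]
    table.columns = ["sum_sq", "df", "F", "p"]
    table.insert(2, "mean_sq", table["sum_sq"] / table["df"])
    return table.loc[["group", "distance", "interaction", "residual"]]


def balanced_anova(values: np.ndarray, group_codes: np.ndarray) -> dict[str, float]:
    """Closed-form two-way ANOVA for a balanced, complete animals x bins matrix.

    Fast path used for Monte-Carlo calibration and the permutation test; agrees
    with :func:`two_way_anova` on balanced designs. *group_codes* assigns each row
    an integer group with equal counts per group.
    """
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise AnalysisError("balanced ANOVA requires a complete matrix")
    codes = np.asarray(group_codes)
    levels = np.unique(codes)
    g, b = len(levels), y.shape[1]
    counts = np.array([(codes == lv).sum() for lv in levels])
    if (counts != counts[0]).any():
        raise AnalysisError("balanced ANOVA requires equal animals per group")
    n = int(counts[0])
    grand = y.mean()
    cell = np.stack([y[codes == lv].mean(axis=0) for lv in levels])  # (g, b)
    gm = cell.mean(axis=1)
    bm = y.mean(axis=0)
    ss_group = n * b * ((gm - grand) ** 2).sum()
    ss_dist = g * n * ((bm - grand) ** 2).sum()
    ss_cells = n * ((cell - grand) ** 2).sum()
    ss_int = ss_cells - ss_group - ss_dist
    resid = y - cell[np.searchsorted(levels, codes)]
    ss_resid = (resid**2).sum()
    df_group, df_dist = g - 1, b - 1
    df_int = df_group * df_dist
    df_resid = g * b * (n - 1)
    if df_resid <= 0:
        raise AnalysisError("zero residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    if ms_resid <= _RESIDUAL_TOL * max(ss_group + ss_dist + ss_int + ss_resid, 1.0):
        raise AnalysisError("residual sum of squares is zero; F statistics undefined")
    out = {
        "ss_group": ss_group, "ss_distance": ss_dist, "ss_interaction": ss_int,
        "ss_residual": ss_resid,
        "df_group": df_group, "df_distance": df_dist, "df_interaction": df_int,
        "df_residual": df_resid,
        "F_group": (ss_group / df_group) / ms_resid,
        "F_distance": (ss_dist / df_dist) / ms_resid,
        "F_interaction": (ss_int / df_int) / ms_resid,
    }
    out["p_group"] = float(sps.f.sf(out["F_group"], df_group, df_resid))
    out["p_distance"] = float(sps.f.sf(out["F_distance"], df_dist, df_resid))
    out["p_interaction"] = float(sps.f.sf(out["F_interaction"], df_int, df_resid))
    return out


def permutation_group_test(
    matrix: ProfileMatrix, n_permutations: int = 10000, seed: int = 0
) -> dict[str, float]:
    """Group-label permutation test of the ANOVA group effect.

    Animals (rows) are the exchangeable units: group labels are permuted across
    rows, the group F statistic recomputed, and the p-value is the add-one
    permutation estimate. Distribution-free companion to :func:`two_way_anova`
    under repeated measures across bins.
    """
    _check_design(matrix)
    levels = matrix.group_levels()
    codes = np.searchsorted(levels, matrix.groups)
    obs = balanced_anova(matrix.values, codes)["F_group"]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f = balanced_anova(matrix.values, perm)["F_group"]
        if f >= obs:
            hits += 1
    return {
        "F_group": float(obs),
        "p_permutation": (1 + hits) / (1 + n_permutations),
        "n_permutations": n_permutations,
    }


@dataclass
class GroupComparison:
    """Two-group comparison at one distance: per-group mean +/- SD, Welch/Student t."""

    distance: float
    group_stats: dict                    # group -> {mean, sd, n}
    difference: float
    statistic: float
    p: float
    method: str = "welch"

    def summary(self) -> str:
        parts = [
            f"{g}: {s['mean']:.2f} ± {s['sd']:.2f}" for g, s in self.group_stats.items()
        ]
        return f"{', '.join(parts)} (mean ± SD), P = {self.p:.4g} at {self.distance:g} um"


def compare_at_distance(
    matrix: ProfileMatrix, distance: float, method: str = "welch"
) -> GroupComparison:
    """Compare the two groups at one distance bin (default Welch two-sample t)."""
    levels = matrix.group_levels()
    if len(levels) != 2:
        raise AnalysisError("pointwise comparison requires exactly 2 groups")
    centers = matrix.bin_centers
    half = 0.5 * (centers[1] - centers[0]) if len(centers) > 1 else 0.5
    exact = np.flatnonzero(np.isclose(centers, distance))
    if exact.size:
        jj = int(exact[0])
    else:
        # snap to the bin containing the distance (half-open [lo, hi) bins)
        inside = np.flatnonzero((distance >= centers - half) & (distance < centers + half))
        if inside.size == 0:
            raise AnalysisError(
                f"distance {distance:g} um is off the bin grid (centers "
                f"{centers[0]:g}..{centers[-1]:g})"
            )
        jj = int(inside[0])
    col = matrix.values[:, jj]
    a = col[matrix.groups == levels[0]]
    b = col[matrix.groups == levels[1]]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("need >= 2 animals per group at this distance")
    if method not in ("welch", "student"):
        raise AnalysisError(f"unknown method {method!r}")
    res = sps.ttest_ind(a, b, equal_var=(method == "student"))
    stats = {
        str(levels[0]): {"mean": float(a.mean()), "sd": float(a.std(ddof=1)), "n": len(a)},
        str(levels[1]): {"mean": float(b.mean()), "sd": float(b.std(ddof=1)), "n": len(b)},
    }
    return GroupComparison(
        distance=float(centers[jj]),
        group_stats=stats,
        difference=float(b.mean() - a.mean()),
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method=method,
    )
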