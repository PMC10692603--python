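"""Grid-based microenvironment definition and statistical comparison.

A square grid (default 170 µm cells) is laid over the field with
letter-row/number-column labels: rows A, B, C … from the top, columns
1, 2, 3 … from the left, so the top-left cell is A1.  A *microenvironment*
is a named set of grid cells plus an inclusive 1-based frame range and a
species; tracks belong to it when their mean position falls inside its
cells (or any spot does, under the ``any`` rule), their frames intersect
the range and the species matches.

Microenvironments are compared metric-by-metric with a one-way ANOVA and
Sidak-adjusted pairwise comparisons (adjusted p = 1 − (1 − p)^m for a
family of m pairwise tests).  Groups below the minimum size are refused —
ANOVA is unreliable for very small samples.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^([A-Z])([0-9]+)$")


@dataclass(frozen=True)
class GridSpec:
    """Square analysis grid anchored at the top-left field corner."""

    cell_side: float = 170.0

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError("cell_side must be > 0")

    def label_for(self, x: float, y: float) -> str:
        """Grid label of the cell containing point (x, y) in µm."""
        row = int(np.floor(y / self.cell_side))
        col = int(np.floor(x / self.cell_side))
        if row < 0 or col < 0:
            raise ValueError(f"point ({x}, {y}) outside the grid")
        if row > 25:
            raise ValueError("field taller than 26 grid rows is unsupported")
        return f"{chr(ord('A') + row)}{col + 1}"

    def parse_label(self, label: str) -> tuple[int, int]:
        """(row, col) 0-based indices of a label such as ``C3``."""
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"malformed grid label {label!r}")
        return ord(m.group(1)) - ord("A"), int(m.group(2)) - 1


@dataclass
class Microenvironment:
    """Named set of grid cells, frame range and species under analysis."""

    name: str
    grid_cells: set[str]
    frame_range: tuple[int, int]
    species: str

    def __post_init__(self) -> None:
        self.grid_cells = set(self.grid_cells)
        if not self.grid_cells:
            raise ValueError(f"microenvironment {self.name!r} has no cells")
        lo, hi = self.frame_range
        if lo < 1 or hi < lo:
            raise ValueError("frame_range must be 1-based and non-empty")


@dataclass
class ComparisonResult:
    """One-way ANOVA plus Sidak-adjusted pairwise comparisons."""

    group_names: list[str]
    group_sizes: list[int]
    F_statistic: float
    anova_p: float
    pairwise: list[tuple[tuple[str, str], float, float]] = \
        dc_field(default_factory=list)
    alpha: float = 0.05


def assign_tracks(tracks: pd.DataFrame, metrics: pd.DataFrame,
                  grid: GridSpec, env: Microenvironment,
                  rule: str = "mean") -> pd.DataFrame:
    """Restrict a metrics table to the tracks belonging to ``env``.

    ``rule='mean'`` uses the track's mean position, ``rule='any'`` accepts
    a track if any of its spots falls in the environment's cells.
    """
    for label in env.grid_cells:
        grid.parse_label(label)
    if rule not in ("mean", "any"):
        raise ValueError("rule must be 'mean' or 'any'")
    sub = tracks[tracks["species"] == env.species]
    lo, hi = env.frame_range
    keep: list[int] = []
    for tid, df in sub.groupby("track_id"):
        frames = df["frame"].to_numpy()
        if frames.max() < lo or frames.min() > hi:
            continue
        if rule == "mean":
            cells = {grid.label_for(df["x_um"].mean(), df["y_um"].mean())}
        else:
            cells = {grid.label_for(x, y)
                     for x, y in df[["x_um", "y_um"]].to_numpy()}
        if cells & env.grid_cells:
            keep.append(tid)
    out = metrics[metrics["track_id"].isin(keep)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(f"microenvironment {env.name!r} matched no tracks",
                      stacklevel=2)
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 − (1 − p)^m, clipped to [0, 1]."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0))


def one_way_anova(groups: list[np.ndarray],
                  names: list[str] | None = None,
                  equal_var: bool = True,
                  min_group_size: int = 2,
                  alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA across ≥ 2 groups with Sidak post hoc pairwise tests.

    F is the between-group over within-group mean square; pairwise raw
    p-values come from two-sample t-tests (Student by default, Welch with
    ``equal_var=False``) and are Sidak-adjusted for the family of all
    pairwise comparisons.  Groups smaller than ``min_group_size`` are
    refused — ANOVA is not meaningful for very small samples.  Identical
    data in all groups (zero total variance) are refused; zero
    within-group variance with unequal means yields F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(groups))]
    for name, g in zip(names, groups):
        if len(g) < max(min_group_size, 2):
            raise ValueError(
                f"group {name!r} has n={len(g)} < {max(min_group_size, 2)}; "
                "refusing ANOVA on very small samples")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ValueError("all values identical; zero total variance")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        F, p = np.inf, 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*groups)
        F, p = float(F), float(p)
        if F < 0.0:  # rounding on identical groups can give -1e-30
            F = 0.0
        if np.isnan(p):
            df_b = len(groups) - 1
            df_w = len(allv) - len(groups)
            p = float(stats.f.sf(F, df_b, df_w))
    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        if within == 0:
            raw = 0.0 if groups[i].mean() != groups[j].mean() else 1.0
        else:
            raw = float(stats.ttest_ind(groups[i], groups[j],
                                        equal_var=equal_var).pvalue)
        pairwise.append(((names[i], names[j]), raw, sidak_adjust(raw, m)))
    return ComparisonResult(group_names=list(names),
                            group_sizes=[len(g) for g in groups],
                            F_statistic=F, anova_p=p,
                            pairwise=pairwise, alpha=alpha)


SUPPORTED_METRICS = ("mean_speed_ums", "confinement_ratio")


def compare_microenvironments(tracks: pd.DataFrame, metrics: pd.DataFrame,
                              grid: GridSpec,
                              env_pairs: list[tuple[Microenvironment,
                                                    Microenvironment]],
                              metric: str = "mean_speed_ums",
                              rule: str = "mean",
                              equal_var: bool = True
                              ) -> list[ComparisonResult]:
    """One ANOVA per microenvironment pair on the chosen track metric."""
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"metric must be one of {SUPPORTED_METRICS}")
    results = []
    for env_a, env_b in env_pairs:
        a = assign_tracks(tracks, metrics, grid, env_a, rule=rule)
        b = assign_tracks(tracks, metrics, grid, env_b, rule=rule)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(
                f"empty microenvironment in pair ({env_a.name!r}, "
                f"{env_b.name!r})")
        res = one_way_anova([a[metric].to_numpy(), b[metric].to_numpy()],
                            names=[env_a.name, env_b.name],
                            equal_var=equal_var)
        results.append(res)
    return results


def plot_metric_histograms(metrics: pd.DataFrame, metric: str,
                           by: str = "species", log10: bool = True,
                           ax=None):
    """Relative-frequency histograms of a metric, one per group.

    With ``log10`` the x axis is logarithmic (zeros dropped), matching the
    usual presentation of area/perimeter/speed distributions.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, df in metrics.groupby(by):
        vals = df[metric].to_numpy()
        if log10:
            vals = vals[vals > 0]
        if len(vals) == 0:
            continue
        bins = (np.logspace(np.log10(vals.min()), np.log10(vals.max()), 30)
                if log10 and vals.min() < vals.max() else 30)
        ax.hist(vals, bins=bins, weights=np.full(len(vals), 100.0 / len(vals)),
                alpha=0.5, label=str(name))
    if log10:
        ax.set_xscale("log")
    ax.set_xlabel(metric)
    ax.set_ylabel("relative frequency (%)")
    ax.legend()
    return ax
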