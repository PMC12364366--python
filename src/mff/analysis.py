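"""Post-processing: implant-vicinity counting, secretion summaries,
ANOVA with Bonferroni correction, and the chemotaxis power-law fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cells import F0, F1, M0, MINT

__all__ = [
    "CountingGeometry",
    "PowerLawFit",
    "count_cells_in_areas",
    "secretion_summary",
    "anova_bonferroni",
    "fit_power_law",
]


@dataclass
class CountingGeometry:
    """Collection areas around a central implant.

    Three 3x3 squares per side, stacked outward along a 13-pixel line
    from the implant edge: a 2-pixel gap (smoothed skirt), the nearest
    square (rank 3), a 1-pixel gap, rank 2, another gap, and the
    farthest square (rank 1); the cross-line window is 3 pixels centred
    on the implant midline.  Four sides give 12 areas, four per
    distance rank.
    """

    grid_n: int = 40
    implant_extent: int = 14
    #: pixels between the implant edge and the nearest square
    skirt_gap: int = 2
    #: list of (rank, side, row_slice, col_slice)
    areas: list = field(default_factory=list)
    implant_mask: np.ndarray = None

    def __post_init__(self):
        if self.areas:
            return
        n, e = self.grid_n, self.implant_extent
        lo = (n - e) // 2
        hi = lo + e - 1
        mid = (lo + hi) // 2  # even extent: window at mid-1 .. mid+1
        cross = slice(mid - 1, mid + 2)
        self.implant_mask = np.zeros((n, n), dtype=bool)
        self.implant_mask[lo:hi + 1, lo:hi + 1] = True
        for rank in (3, 2, 1):
            # outward offset of the square's near edge from the implant
            off = self.skirt_gap + (3 - rank) * 4
            a, b = lo - off - 3, lo - off  # above/left of the implant
            c, d = hi + 1 + off, hi + 1 + off + 3
            if a < 0 or d > n:
                raise ValueError("counting areas fall outside the grid")
            self.areas.append((rank, "top", slice(a, b), cross))
            self.areas.append((rank, "bottom", slice(c, d), cross))
            self.areas.append((rank, "left", cross, slice(a, b)))
            self.areas.append((rank, "right", cross, slice(c, d)))
        for rank, side, rs, cs in self.areas:
            if self.implant_mask[rs, cs].any():
                raise ValueError("counting area overlaps the implant")


def count_cells_in_areas(final_state, geometry: CountingGeometry,
                         pool_f0: bool = False) -> pd.DataFrame:
    """Count macrophages and fibroblasts per distance rank.

    Macrophage counts pool every macrophage state (M0, M1, M2 and
    intermediate); the fibroblast count is F1 only by default, with F0
    reported separately (``pool_f0=True`` merges them).  Cells sitting
    on the implant mask are counted in no area.  Returns a frame
    indexed by rank with columns ``macrophages``, ``fibroblasts``,
    ``fibrocytes``.
    """
    if final_state.occ.shape != (geometry.grid_n, geometry.grid_n):
        raise ValueError("geometry grid does not match the state grid")
    phen_grid = np.full((geometry.grid_n, geometry.grid_n), -1, dtype=np.int8)
    if final_state.n_cells:
        phen_grid[final_state.xs, final_state.ys] = final_state.phen
    rows = {r: {"macrophages": 0, "fibroblasts": 0, "fibrocytes": 0}
            for r in (1, 2, 3)}
    for rank, _side, rs, cs in geometry.areas:
        patch = phen_grid[rs, cs]
        rows[rank]["macrophages"] += int(((patch >= M0)
                                          & (patch <= MINT)).sum())
        rows[rank]["fibroblasts"] += int((patch == F1).sum())
        rows[rank]["fibrocytes"] += int((patch == F0).sum())
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "rank"
    if pool_f0:
        df["fibroblasts"] += df["fibrocytes"]
    return df


def secretion_summary(traces_by_condition: dict) -> pd.DataFrame:
    """Time-averaged mean cumulative secreted PIM/AIM per condition.

    For each condition the cumulative-secretion kinetics are averaged
    across runs step-wise, then averaged over time points.  Input maps
    condition name to a list of traces (or trace DataFrames).
    """
    if not traces_by_condition:
        raise ValueError("no conditions supplied")
    out = {}
    for cond, traces in traces_by_condition.items():
        if not traces:
            raise ValueError(f"condition {cond!r} has no traces")
        frames = [t.data if hasattr(t, "data") else t for t in traces]
        pim = np.mean([f["cum_pim"].to_numpy() for f in frames], axis=0)
        aim = np.mean([f["cum_aim"].to_numpy() for f in frames], axis=0)
        out[cond] = {"pim": float(pim.mean()), "aim": float(aim.mean())}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "condition"
    return df


def per_run_time_averages(traces, column: str) -> np.ndarray:
    """One time-averaged scalar per run (the ANOVA per-run summary)."""
    frames = [t.data if hasattr(t, "data") else t for t in traces]
    return np.array([float(f[column].mean()) for f in frames])


def anova_bonferroni(groups):
    """One-way ANOVA plus pairwise Bonferroni-adjusted comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps the index pair
    ``(i, j)`` to the two-sample t-test p-value multiplied by the
    number of comparisons (capped at 1).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    f_stat, p_val = stats.f_oneway(*groups)
    if math.isnan(f_stat):  # all groups identical and constant
        f_stat, p_val = 0.0, 1.0
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, p = stats.ttest_ind(groups[i], groups[j])
            if math.isnan(p):
                p = 1.0
            pairwise[(i, j)] = min(1.0, float(p) * m)
    return float(f_stat), float(p_val), pairwise


@dataclass
class PowerLawFit:
    """N_c ~ A * k^m with standard errors from the log-log fit."""

    A: float
    m: float
    A_se: float
    m_se: float
    n_points: int
    n_excluded: int = 0


def fit_power_law(k_values, nc_values) -> PowerLawFit:
    """Least-squares fit of log N_c against log k.

    Points with k <= 0 are excluded (the power law is undefined there);
    at least two usable points are required.
    """
    k = np.asarray(k_values, dtype=np.float64)
    nc = np.asarray(nc_values, dtype=np.float64)
    if k.shape != nc.shape:
        raise ValueError("k and N_c must have the same length")
    usable = k > 0
    n_excluded = int((~usable).sum())
    k, nc = k[usable], nc[usable]
    if k.size < 2:
        raise ValueError("need at least two points with k > 0")
    if np.any(nc <= 0):
        raise ValueError("N_c must be positive for a log-log fit")
    x, y = np.log(k), np.log(nc)
    if k.size == 2:
        m = (y[1] - y[0]) / (x[1] - x[0])
        return PowerLawFit(float(np.exp(y[0] - m * x[0])), float(m),
                           float("nan"), float("nan"), 2, n_excluded)
    coef, cov = np.polyfit(x, y, 1, cov=True)
    m, loga = coef
    m_se, loga_se = np.sqrt(np.diag(cov))
    A = float(np.exp(loga))
    return PowerLawFit(A, float(m), A * float(loga_se), float(m_se),
                       int(k.size), n_excluded)
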