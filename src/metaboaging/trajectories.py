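"""Protein trajectories along metabolic age.

Per-protein LOESS (local linear regression, tricube weights over the
span-fraction nearest neighbours) evaluated on a fixed MA grid; Euclidean
distance between smoothed curves; agglomerative Ward clustering cut to k
groups with deterministic renumbering (ascending cluster-mean value at the
grid midpoint); and Mann-Kendall monotone-trend tests with tie-corrected
variance and continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

DEFAULT_GRID = np.arange(40.0, 70.0 + 1e-9, 0.5)


def fit_loess_trajectory(y, x, span: float = 0.5, grid=None) -> np.ndarray:
    """LOESS curve of y against x evaluated at ``grid``.

    Degree-1 weighted least squares in each neighbourhood of the
    ``ceil(span * n)`` nearest observations, tricube weights
    ``(1 - (d/h)^3)^3``.  Grid points outside the observed x range raise
    (no extrapolation).  Exact on constant and linear signals.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 20:
        raise ValueError("need at least 20 observations for a trajectory")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, float)
    if grid.min() < x.min() or grid.max() > x.max():
        raise ValueError("grid extends beyond the observed range; "
                         "no extrapolation")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = xs.size
    r = max(2, int(np.ceil(span * n)))
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, r - 1)[:r]
        h = d[idx].max()
        if h == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1.0 - np.clip(d[idx] / h, 0, 1) ** 3) ** 3
        xi, yi = xs[idx], ys[idx]
        sw = w.sum()
        xm = (w * xi).sum() / sw
        ym = (w * yi).sum() / sw
        sxx = (w * (xi - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            out[i] = ym
        else:
            slope = (w * (xi - xm) * (yi - ym)).sum() / sxx
            out[i] = ym + slope * (g - xm)
    return out


def mann_kendall(values):
    """Mann-Kendall trend test.

    S = sum_{i<j} sign(v_j - v_i); Var(S) with the tie correction
    n(n-1)(2n+5)/18 - sum t(t-1)(2t+5)/18; z uses the +/-1 continuity
    correction (0 when S = 0); two-sided normal p.
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values")
    s = int(np.sign(v[None, :] - v[:, None])[np.triu_indices(n, 1)].sum())
    _, tie_counts = np.unique(v, return_counts=True)
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var_s <= 0:
        warnings.warn("all values tied; no trend information", RuntimeWarning)
        return 0, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(p)


@dataclass
class TrajectorySet:
    grid: np.ndarray
    curves: pd.DataFrame          # proteins x grid points
    span: float
    mk: pd.DataFrame              # per protein: S, var_s, z, p
    labels: pd.Series = None
    linkage_matrix: np.ndarray = None


def fit_trajectories(proteins: pd.DataFrame, ma, span: float = 0.5,
                     grid=None, standardize: bool = True) -> TrajectorySet:
    """LOESS curve and Mann-Kendall trend (on the smoothed curve) per
    protein column."""
    ma = np.asarray(ma, float)
    if grid is None:
        lo = max(DEFAULT_GRID.min(), np.ceil(ma.min() * 2) / 2)
        hi = min(DEFAULT_GRID.max(), np.floor(ma.max() * 2) / 2)
        grid = np.arange(lo, hi + 1e-9, 0.5)
    grid = np.asarray(grid, float)
    vals = proteins.astype(float)
    if standardize:
        vals = (vals - vals.mean()) / vals.std(ddof=1)
    curves = {}
    mk_rows = {}
    for name in vals.columns:
        curve = fit_loess_trajectory(vals[name].to_numpy(), ma, span=span,
                                     grid=grid)
        curves[name] = curve
        s, var_s, z, p = mann_kendall(curve)
        mk_rows[name] = {"S": s, "var_s": var_s, "z": z, "p": p}
    curve_df = pd.DataFrame(curves, index=grid).T
    return TrajectorySet(grid=grid, curves=curve_df, span=span,
                         mk=pd.DataFrame(mk_rows).T)


def cluster_trajectories(curves: pd.DataFrame, k: int = 3):
    """Ward clustering of curve vectors (Euclidean distance), cut to k
    clusters, labels renumbered by ascending cluster-mean curve value at
    the grid midpoint."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if curves.shape[0] < k:
        raise ValueError(f"fewer curves ({curves.shape[0]}) than clusters ({k})")
    X = curves.to_numpy(float)
    if k == 1:
        return (pd.Series(1, index=curves.index), None)
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    mid = X.shape[1] // 2
    means = {lab: X[raw == lab, mid].mean() for lab in np.unique(raw)}
    order = sorted(means, key=lambda lab: means[lab])
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = pd.Series([remap[lab] for lab in raw], index=curves.index)
    return labels, Z


def assign_trajectory_groups(traj: TrajectorySet, k: int = 3) -> TrajectorySet:
    labels, Z = cluster_trajectories(traj.curves, k=k)
    traj.labels = labels
    traj.linkage_matrix = Z
    return traj
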