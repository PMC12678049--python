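"""Sliding-window differential expression along metabolic age.

At each MA center c (default integer centers 40..70, 31 values) the
participants with |MA - c| <= 1.5 years form a window; those with MA < c
are the "low" group and MA >= c the "high" group.  Per protein the linear
model

    protein = alpha + beta1 * I(high) + covariates + eps

is fitted inside the window, and the per-center family of protein tests is
Bonferroni-corrected (FDR available as a sensitivity option).  Local
maxima of the per-center count of significant proteins are the protein
"waves"; their differentially-expressed sets are compared with an
upset-style exclusive partition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pwas import bh_fdr, bonferroni

DEFAULT_CENTERS = tuple(range(40, 71))
DEFAULT_HALFWIDTH = 1.5


@dataclass
class DeswanGrid:
    table: pd.DataFrame          # center, protein, beta1, se, p, p_adj, n_low, n_high
    centers: np.ndarray
    halfwidth: float
    correction: str
    skipped_centers: list = field(default_factory=list)

    def at_center(self, center) -> pd.DataFrame:
        return self.table[self.table["center"] == center].set_index("protein")


def window_groups(ma, center, halfwidth=DEFAULT_HALFWIDTH):
    """Window membership |MA - c| <= halfwidth (ties included) and the
    low/high split at the center (MA < c -> low, MA >= c -> high)."""
    ma = np.asarray(ma, float)
    inside = np.abs(ma - center) <= halfwidth
    high = ma >= center
    return inside, high


def deswan_scan(proteins: pd.DataFrame, ma, covariates=None,
                centers=DEFAULT_CENTERS, halfwidth=DEFAULT_HALFWIDTH,
                correction: str = "bonferroni", min_n: int = 30) -> DeswanGrid:
    """Low/high contrast per (center, protein) with covariate adjustment."""
    if correction not in ("bonferroni", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    ma = np.asarray(ma, float)
    if not np.all(np.isfinite(ma)):
        raise ValueError("metabolic age must be finite")
    P = proteins.to_numpy(float)
    cov = (np.empty((len(ma), 0)) if covariates is None
           else np.asarray(covariates, float))
    rows = []
    skipped = []
    for c in centers:
        inside, high = window_groups(ma, c, halfwidth)
        n_low = int((inside & ~high).sum())
        n_high = int((inside & high).sum())
        if (n_low + n_high) < min_n or n_low == 0 or n_high == 0:
            warnings.warn(f"center {c}: window too small or single group; "
                          "skipped", RuntimeWarning)
            skipped.append(c)
            continue
        g = high[inside].astype(float)
        C = np.c_[np.ones(g.size), cov[inside]]
        Pw = P[inside]
        # residualise the group indicator and the proteins on the covariates
        Q, _ = np.linalg.qr(C)
        gt = g - Q @ (Q.T @ g)
        EP = Pw - Q @ (Q.T @ Pw)
        sgg = float(gt @ gt)
        if sgg <= 1e-12:
            skipped.append(c)
            continue
        beta1 = (gt @ EP) / sgg
        resid = EP - np.outer(gt, beta1)
        df = g.size - C.shape[1] - 1
        if df <= 0:
            skipped.append(c)
            continue
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(sigma2 / sgg)
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = beta1 / se
        p = 2.0 * stats.t.sf(np.abs(tv), df)
        adj = bonferroni(p) if correction == "bonferroni" else bh_fdr(p)
        for j, name in enumerate(proteins.columns):
            rows.append((c, name, beta1[j], se[j], p[j], adj[j],
                         n_low, n_high))
    table = pd.DataFrame(rows, columns=["center", "protein", "beta1", "se",
                                        "p", "p_adj", "n_low", "n_high"])
    return DeswanGrid(table=table, centers=np.asarray(list(centers), float),
                      halfwidth=float(halfwidth), correction=correction,
                      skipped_centers=skipped)


def count_significant(grid: DeswanGrid, alpha: float = 0.05) -> pd.Series:
    """Per-center count of proteins with adjusted p < alpha (skipped
    centers count 0)."""
    sig = grid.table[grid.table["p_adj"] < alpha]
    counts = sig.groupby("center").size()
    return counts.reindex(grid.centers, fill_value=0).astype(int)


def detect_peaks(counts: pd.Series, min_count: int = 1) -> list:
    """Strict local maxima of the count curve.

    A run of equal values higher than both neighbours is a peak at its
    leftmost center; boundary runs qualify when higher than their single
    neighbour; peaks below ``min_count`` are dropped.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 centers to detect peaks")
    v = counts.to_numpy(float)
    cen = counts.index.to_numpy()
    peaks = []
    i = 0
    n = len(v)
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        at_both_bounds = i == 0 and j == n - 1
        if left_ok and right_ok and not at_both_bounds and v[i] >= min_count:
            peaks.append(cen[i])
        i = j + 1
    return peaks


def significant_sets(grid: DeswanGrid, peaks, alpha: float = 0.05) -> dict:
    """Differentially-expressed protein set at each peak center."""
    out = {}
    for c in peaks:
        tab = grid.at_center(c)
        out[c] = set(tab.index[tab["p_adj"] < alpha])
    return out


@dataclass
class PeakSet:
    peak_centers: list
    protein_sets: dict            # center -> set
    overlap: pd.DataFrame         # upset-style exclusive partition


def peak_overlap(protein_sets: dict) -> pd.DataFrame:
    """Exclusive (upset-style) partition over every nonempty combination of
    peaks; cell sizes sum to the size of the union."""
    if len(protein_sets) < 2:
        raise ValueError("need at least 2 peaks for an overlap table")
    peaks = sorted(protein_sets)
    rows = []
    for r in range(1, len(peaks) + 1):
        for combo in itertools.combinations(peaks, r):
            inside = set.intersection(*(protein_sets[c] for c in combo))
            outside = set.union(*(protein_sets[c] for c in peaks
                                  if c not in combo), set())
            excl = inside - outside
            rows.append({"peaks": combo, "n": len(excl),
                         "proteins": tuple(sorted(excl))})
    return pd.DataFrame(rows)


def build_peakset(grid: DeswanGrid, alpha: float = 0.05,
                  min_count: int = 1) -> PeakSet:
    counts = count_significant(grid, alpha)
    peaks = detect_peaks(counts, min_count=min_count)
    sets = significant_sets(grid, peaks, alpha)
    overlap = peak_overlap(sets) if len(peaks) >= 2 else pd.DataFrame(
        columns=["peaks", "n", "proteins"])
    return PeakSet(peak_centers=list(peaks), protein_sets=sets,
                   overlap=overlap)
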