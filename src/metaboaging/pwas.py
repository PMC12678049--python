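"""Proteome-wide association scans across six metabolic-aging phenotypes.

Continuous phenotypes (MA, frailty index, telomere length) are scanned
with per-protein linear models (phenotype ~ protein + covariates, effect
per SD of protein); time-to-event phenotypes (death, CVD, T2D) with
per-protein Cox models.  Bonferroni adjustment is applied within each
phenotype over the proteins scanned; Benjamini-Hochberg is available as a
sensitivity option.  Proteins significant in all six scans form the
metabolic-aging-related set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import fit_cox

COX_PHENOTYPES = ("death", "cvd", "t2d")
LINEAR_PHENOTYPES = ("ma", "fi", "telomere")


class ScanError(ValueError):
    pass


@dataclass
class PhenotypeSpec:
    name: str
    model: str       # {"linear", "cox"}

    def __post_init__(self):
        key = self.name.lower()
        if key in COX_PHENOTYPES and self.model != "cox":
            raise ScanError(f"{self.name} must use a cox model")
        if key in LINEAR_PHENOTYPES and self.model != "linear":
            raise ScanError(f"{self.name} must use a linear model")
        if self.model not in ("linear", "cox"):
            raise ScanError(f"unknown model {self.model!r}")


def bonferroni(p, m=None):
    p = np.asarray(p, float)
    m = p.size if m is None else int(m)
    return np.minimum(1.0, p * m)


def bh_fdr(p):
    """Benjamini-Hochberg adjusted p-values (monotone after sorting)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScanResult:
    phenotype: str
    table: pd.DataFrame        # index protein; effect, se, p, p_bonf, p_fdr, n
    m: int                     # number of tests corrected for
    failures: dict             # protein -> reason

    @property
    def proteins(self):
        return set(self.table.index)

    def significant(self, alpha=0.05, column="p_bonf"):
        return set(self.table.index[self.table[column] < alpha])


def _linear_scan(proteins: pd.DataFrame, y, covariates):
    """Vectorised per-protein OLS of y on [protein, intercept+covariates].

    Frisch-Waugh: residualise y and every protein on the covariates; the
    protein coefficient and its SE from the full model follow from the
    residualised simple regressions with df = n - p_cov - 1.
    """
    P = proteins.to_numpy(float)
    y = np.asarray(y, float)
    C = np.c_[np.ones(len(y)), np.asarray(covariates, float)]
    n, pc = C.shape
    Q, _ = np.linalg.qr(C)
    ey = y - Q @ (Q.T @ y)
    EP = P - Q @ (Q.T @ P)
    spp = np.einsum("ij,ij->j", EP, EP)
    spy = EP.T @ ey
    ok = spp > 1e-12
    beta = np.where(ok, spy / np.where(ok, spp, 1.0), np.nan)
    rss = ey @ ey - np.where(ok, beta**2 * spp, 0.0)
    df = n - pc - 1
    sigma2 = rss / df
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, spp, 1.0), np.nan))
    tvals = beta / se
    p = 2.0 * stats.t.sf(np.abs(tvals), df)
    failures = {proteins.columns[j]: "zero residual variance"
                for j in np.flatnonzero(~ok)}
    return beta, se, p, failures


def scan_proteins(proteins: pd.DataFrame, spec: PhenotypeSpec, covariates,
                  outcome=None, phenotype_values=None,
                  m: int = None) -> ScanResult:
    """One model per protein; effects are per 1 SD of (standardized)
    protein.  Per-protein model failures are recorded, not fatal."""
    cov = np.asarray(covariates, float)
    if spec.model == "linear":
        if phenotype_values is None:
            raise ScanError("linear scan needs phenotype_values")
        beta, se, p, failures = _linear_scan(proteins, phenotype_values, cov)
        n_used = np.full(proteins.shape[1], len(proteins))
    else:
        if outcome is None:
            raise ScanError("cox scan needs an outcome table")
        t = outcome["time"].to_numpy(float)
        e = outcome["event"].to_numpy(float)
        beta = np.full(proteins.shape[1], np.nan)
        se = np.full(proteins.shape[1], np.nan)
        p = np.full(proteins.shape[1], np.nan)
        failures = {}
        for j, name in enumerate(proteins.columns):
            X = np.c_[proteins.iloc[:, j].to_numpy(float), cov]
            try:
                fit = fit_cox(t, e, X)
            except Exception as exc:     # degenerate protein must not kill the scan
                failures[name] = str(exc)
                continue
            beta[j], se[j], p[j] = fit.coef[0], fit.se[0], fit.p[0]
        n_used = np.full(proteins.shape[1], len(proteins))
    tab = pd.DataFrame({"effect": beta, "se": se, "p": p, "n": n_used},
                       index=proteins.columns)
    tab = tab[~tab["p"].isna()]
    m_eff = tab.shape[0] if m is None else m
    tab["p_bonf"] = bonferroni(tab["p"].to_numpy(), m_eff)
    tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
    return ScanResult(phenotype=spec.name, table=tab, m=m_eff,
                      failures=failures)


def intersect_significant(scans: dict, alpha: float = 0.05):
    """Proteins Bonferroni-significant in every scan, plus the per-protein
    count of significant phenotypes."""
    universes = [s.proteins | set(s.failures) for s in scans.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ScanError("scans cover different protein universes")
    sigs = {name: s.significant(alpha) for name, s in scans.items()}
    inter = set.intersection(*sigs.values()) if sigs else set()
    all_prot = sorted(universes[0]) if universes else []
    counts = pd.DataFrame(
        {name: [p in sig for p in all_prot] for name, sig in sigs.items()},
        index=all_prot).astype(int)
    counts["n_significant"] = counts.sum(axis=1)
    return inter, counts


def rank_top(scan: ScanResult, k: int = 20, universe=None) -> list:
    """Top-k proteins by ascending Bonferroni-adjusted p; ties broken by raw
    p, then |effect| (larger first), then label."""
    tab = scan.table
    if universe is not None:
        missing = set(universe) - set(tab.index)
        if missing:
            raise ScanError(f"universe proteins absent from scan: {sorted(missing)[:5]}")
        tab = tab.loc[tab.index.isin(set(universe))]
    order = sorted(
        tab.index,
        key=lambda pr: (tab.at[pr, "p_bonf"], tab.at[pr, "p"],
                        -abs(tab.at[pr, "effect"]), pr))
    return order[:k]


def replication_concordance(train: ScanResult, val: ScanResult,
                            alpha: float = 0.05) -> dict:
    """Among train-significant proteins: the fraction also significant in
    the validation scan with the same effect sign, and the fraction with
    the same sign regardless of significance."""
    shared = train.proteins & val.proteins
    tr_sig = train.significant(alpha) & shared
    if not tr_sig:
        return {"n_train_significant": 0, "replicated_fraction": None,
                "sign_consistent_fraction": None}
    prot = sorted(tr_sig)
    tr_eff = train.table.loc[prot, "effect"]
    va_eff = val.table.loc[prot, "effect"]
    same_sign = np.sign(tr_eff.to_numpy()) == np.sign(va_eff.to_numpy())
    va_sig = np.array([p in val.significant(alpha) for p in prot])
    return {
        "n_train_significant": len(prot),
        "replicated_fraction": float(np.mean(va_sig & same_sign)),
        "sign_consistent_fraction": float(np.mean(same_sign)),
    }
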