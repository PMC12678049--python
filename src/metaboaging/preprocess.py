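"""Input preprocessing.

Metabolites are mean-imputed on the raw concentration scale, ln(x + 1)
transformed and z-scored; proteins with more than 30% missing values are
dropped (strictly greater -- a column missing exactly 30% is kept) and the
rest mean-imputed and z-scored; the frailty index is the proportion of
deficits among observed items, with participants missing >= 10 items
excluded; telomere ratios are log-transformed and z-scored; covariates are
median/mode imputed below a 5% missing rate and flagged with an explicit
missing indicator above it.  All z-scores use the sample SD (divisor n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


@dataclass
class MetaboliteMatrix:
    values: pd.DataFrame
    stage: str = "raw"   # {"raw", "transformed"}

    @property
    def biomarker_ids(self):
        return list(self.values.columns)


@dataclass
class ProteinMatrix:
    values: pd.DataFrame
    stage: str = "raw"   # {"raw", "standardized"}

    @property
    def protein_ids(self):
        return list(self.values.columns)


def _zscore(df: pd.DataFrame, context: str) -> pd.DataFrame:
    sd = df.std(ddof=1)
    bad = sd[(sd == 0) | sd.isna()]
    if len(bad):
        raise PreprocessError(
            f"zero-variance column(s) in {context}: {list(bad.index)}")
    return (df - df.mean()) / sd


def transform_metabolites(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Mean-impute raw values per biomarker, then ln(x+1), then z-score."""
    if m.stage != "raw":
        raise PreprocessError("transform_metabolites expects stage='raw'")
    vals = m.values.astype(float)
    if (vals < 0).any().any():
        raise PreprocessError("raw metabolite concentrations must be >= 0")
    entirely = vals.columns[vals.isna().all()]
    if len(entirely):
        raise PreprocessError(
            f"metabolite column(s) entirely missing: {list(entirely)}")
    filled = vals.fillna(vals.mean())
    out = _zscore(np.log1p(filled), "transformed metabolites")
    return MetaboliteMatrix(values=out, stage="transformed")


def filter_proteins(p: ProteinMatrix, max_missing: float = 0.30) -> ProteinMatrix:
    """Drop proteins with missing fraction strictly above ``max_missing``,
    mean-impute the remainder and z-score."""
    if p.stage != "raw":
        raise PreprocessError("filter_proteins expects stage='raw'")
    vals = p.values.astype(float)
    frac = vals.isna().mean()
    keep = frac[frac <= max_missing].index
    if len(keep) == 0:
        raise PreprocessError("all protein columns exceed the missingness "
                              "threshold")
    kept = vals[keep]
    out = _zscore(kept.fillna(kept.mean()), "standardized proteins")
    return ProteinMatrix(values=out, stage="standardized")


def compute_frailty_index(items: pd.DataFrame, n_items: int = 49,
                          max_missing_items: int = 10,
                          denominator: str = "observed") -> pd.DataFrame:
    """Frailty index per participant.

    FI = (sum of observed deficit scores) / (number of observed items) by
    default; ``denominator="fixed"`` divides by ``n_items`` instead.
    Participants with >= ``max_missing_items`` missing items are flagged
    excluded and get no FI.
    """
    if items.shape[1] != n_items:
        raise PreprocessError(
            f"expected {n_items} deficit items, got {items.shape[1]} "
            "(override n_items to accept)")
    vals = items.astype(float)
    if ((vals < 0) | (vals > 1)).any().any():
        raise PreprocessError("deficit items must be coded in [0, 1]")
    n_missing = vals.isna().sum(axis=1)
    denom = (vals.notna().sum(axis=1) if denominator == "observed"
             else float(n_items))
    fi = vals.sum(axis=1) / denom
    excluded = n_missing >= max_missing_items
    fi[excluded] = np.nan
    return pd.DataFrame({"fi": fi, "n_missing_items": n_missing,
                         "excluded": excluded})


def prepare_telomere(raw: pd.Series) -> pd.Series:
    """Natural log then z-score; input ratios are assumed technically
    pre-adjusted."""
    raw = raw.astype(float)
    if (raw <= 0).any():
        raise PreprocessError("telomere ratios must be positive")
    logged = np.log(raw)
    sd = logged.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise PreprocessError("telomere column has zero variance")
    return (logged - logged.mean()) / sd


@dataclass
class CovariateImputation:
    table: pd.DataFrame
    audit: dict = field(default_factory=dict)   # field -> method record


def impute_covariates(c: pd.DataFrame, categorical=None,
                      indicator_threshold: float = 0.05) -> CovariateImputation:
    """Median (continuous) / mode (categorical) fill when the missing rate is
    <= 5%; above that, categorical fields get a dedicated "missing" level
    and continuous fields a binary indicator column plus median fill."""
    out = c.copy()
    audit = {}
    if categorical is None:
        categorical = [col for col in c.columns
                       if not pd.api.types.is_float_dtype(c[col].dtype)
                       or c[col].dropna().nunique() <= 2]
    for col in c.columns:
        rate = float(c[col].isna().mean())
        if rate == 0:
            audit[col] = {"method": "none", "missing_rate": 0.0}
            continue
        if rate == 1.0:
            raise PreprocessError(f"covariate {col!r} is entirely missing")
        is_cat = col in categorical
        if rate <= indicator_threshold:
            if is_cat:
                fill = c[col].mode(dropna=True).iloc[0]
                method = "mode"
            else:
                fill = c[col].median(skipna=True)
                method = "median"
            out[col] = c[col].fillna(fill)
            audit[col] = {"method": method, "missing_rate": rate,
                          "fill": fill}
        else:
            if is_cat:
                out[col] = c[col].astype(object).where(c[col].notna(),
                                                       "missing")
                audit[col] = {"method": "missing_category",
                              "missing_rate": rate}
            else:
                ind = f"{col}_missing"
                out[ind] = c[col].isna().astype(int)
                out[col] = c[col].fillna(c[col].median(skipna=True))
                audit[col] = {"method": "indicator+median",
                              "missing_rate": rate, "indicator": ind}
    return CovariateImputation(table=out, audit=audit)


def landmark_filter(outcome: pd.DataFrame, years: float = 1.0) -> pd.DataFrame:
    """Drop participants whose event occurred before ``years`` of follow-up.

    Early censorings are retained; the exclusion targets incident cases
    only (reverse-causation guard)."""
    if (outcome["time"] <= 0).any():
        raise PreprocessError("follow-up times must be positive")
    early_event = (outcome["event"] == 1) & (outcome["time"] < years)
    return outcome.loc[~early_event]


def encode_design(cov: pd.DataFrame, drop=("center",)) -> pd.DataFrame:
    """Numeric model matrix from an imputed covariate table (dummy-coded
    object columns, drop-first)."""
    use = cov.drop(columns=[c for c in drop if c in cov], errors="ignore")
    obj = [c for c in use.columns if use[c].dtype == object]
    mat = pd.get_dummies(use, columns=obj, drop_first=True, dtype=float)
    return mat.astype(float)
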