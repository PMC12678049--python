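"""Metabolic age (MA) construction and validation.

The clock rests on the Gompertz proportional-hazards mortality model
h(t | x) = b * exp(gamma * t) * exp(x'beta) on the age timescale.  A
participant's metabolite score s = x'beta (centered) shifts their log
hazard; the metabolic age is the age m at which the population-average
hazard (score 0) equals the participant's predicted hazard at their own
chronological age CA:

    b * exp(gamma * m) = b * exp(gamma * CA + s)   =>   m = CA + s / gamma.

Metabolic age acceleration (MAA) is the residual from OLS of MA on CA; a
positive residual marks a metabolically older participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import (GompertzFit, SurvivalError, fit_cox, fit_gompertz_ph,
                       fit_penalized_cox, harrell_c)


class MAError(ValueError):
    pass


@dataclass
class MetaboliteSelection:
    indices: np.ndarray        # into the metabolite columns, ranked by |beta|
    names: list
    betas: np.ndarray          # penalized coefficients, same order
    fit: object                # PenalizedCoxFit
    rule_used: str


def select_ma_metabolites(metabolites: pd.DataFrame, time, event,
                          covariates=None, folds: int = 10,
                          rule: str = "lambda_1se", seed: int = 0,
                          fallback_to_min: bool = True) -> MetaboliteSelection:
    """LASSO-Cox selection of mortality-associated metabolites.

    The penalty applies to the metabolite block only; covariates are
    unpenalized.  Metabolites with a nonzero coefficient at the chosen
    lambda are returned ranked by |coefficient| (descending).
    """
    X_pen = metabolites.to_numpy(float)
    X_unpen = None if covariates is None else np.asarray(covariates, float)
    fit = fit_penalized_cox(time, event, X_pen, X_unpen, folds=folds,
                            rule=rule, seed=seed)
    rule_used = rule
    sel = fit.selected_features
    if sel.size == 0 and rule == "lambda_1se" and fallback_to_min:
        jmin = int(np.argmin(np.abs(fit.lambda_path - fit.lambda_min)))
        coef_min = fit.coef_path[:fit.n_penalized, jmin]
        sel = np.flatnonzero(coef_min != 0)
        fit.coef = fit.coef_path[:, jmin].copy()
        rule_used = "lambda_min(fallback)"
    if sel.size == 0:
        raise MAError("LASSO selected no metabolites; consider rule="
                      "'lambda_min'")
    betas = fit.coef[sel]
    order = np.argsort(-np.abs(betas), kind="mergesort")
    sel, betas = sel[order], betas[order]
    return MetaboliteSelection(
        indices=sel, names=[metabolites.columns[j] for j in sel],
        betas=betas, fit=fit, rule_used=rule_used)


def compute_metabolic_age(score, chronological_age, gompertz) -> np.ndarray:
    """MA_i = CA_i + score_i / gamma (gamma from the Gompertz fit)."""
    gamma = gompertz.gamma if isinstance(gompertz, GompertzFit) else float(gompertz)
    if gamma <= 0:
        raise MAError("gamma must be positive to map a score onto years")
    return np.asarray(chronological_age, float) + np.asarray(score, float) / gamma


def compute_maa(ma, chronological_age):
    """OLS residual of MA on CA (with intercept) and the accelerated flag."""
    ma = np.asarray(ma, float)
    ca = np.asarray(chronological_age, float)
    if ma.shape != ca.shape:
        raise MAError("ma and chronological_age lengths differ")
    if ma.size < 3:
        raise MAError("need at least 3 participants")
    if np.ptp(ca) == 0:
        raise MAError("chronological age is constant; regression undefined")
    A = np.c_[np.ones_like(ca), ca]
    coef, *_ = np.linalg.lstsq(A, ma, rcond=None)
    maa = ma - A @ coef
    return maa, maa > 0


@dataclass
class MAResult:
    score: np.ndarray
    ma: np.ndarray
    maa: np.ndarray
    accelerated: np.ndarray
    gompertz: GompertzFit
    selection: MetaboliteSelection = None

    def frame(self, index) -> pd.DataFrame:
        return pd.DataFrame({"score": self.score, "ma": self.ma,
                             "maa": self.maa,
                             "accelerated": self.accelerated.astype(int)},
                            index=index)


def estimate_metabolic_age(metabolites: pd.DataFrame, entry_age, time, event,
                           selection: MetaboliteSelection = None,
                           metabolite_columns=None) -> MAResult:
    """Fit the Gompertz PH model on the selected metabolites and convert the
    fitted score into metabolic age.

    ``metabolite_columns`` may name the metabolite set directly (e.g. the
    ground-truth causal set in recovery experiments); otherwise the columns
    come from a prior LASSO ``selection``.
    """
    if metabolite_columns is None:
        if selection is None:
            raise MAError("either selection or metabolite_columns required")
        metabolite_columns = selection.names
    X = metabolites[list(metabolite_columns)].to_numpy(float)
    entry = np.asarray(entry_age, float)
    exit_age = entry + np.asarray(time, float)
    gfit = fit_gompertz_ph(entry, exit_age, event, X,
                           terms=list(metabolite_columns))
    score = X @ gfit.beta
    score = score - score.mean()
    ma = compute_metabolic_age(score, entry, gfit)
    maa, acc = compute_maa(ma, entry)
    return MAResult(score=score, ma=ma, maa=maa, accelerated=acc,
                    gompertz=gfit, selection=selection)


def apply_metabolic_age(metabolites: pd.DataFrame, chronological_age,
                        result: MAResult) -> MAResult:
    """Score a new cohort with an already-fitted clock (same columns,
    same centering population is approximated by re-centering)."""
    cols = result.gompertz.terms
    X = metabolites[cols].to_numpy(float)
    score = X @ result.gompertz.beta
    score = score - score.mean()
    ma = compute_metabolic_age(score, chronological_age, result.gompertz)
    maa, acc = compute_maa(ma, chronological_age)
    return MAResult(score=score, ma=ma, maa=maa, accelerated=acc,
                    gompertz=result.gompertz, selection=result.selection)


@dataclass
class MAValidationReport:
    c_index_base: dict
    c_index_base_plus_ma: dict
    hr_accelerated: dict          # endpoint -> (hr, lo, hi, p)
    beta_telomere: tuple          # (beta, lo, hi, p)
    beta_fi: tuple
    spearman_ma_ca: float
    mae_ma_ca: float

    def to_dict(self):
        return {
            "c_index_base": self.c_index_base,
            "c_index_base_plus_ma": self.c_index_base_plus_ma,
            "hr_accelerated": {k: list(v) for k, v in self.hr_accelerated.items()},
            "beta_telomere": list(self.beta_telomere),
            "beta_fi": list(self.beta_fi),
            "spearman_ma_ca": self.spearman_ma_ca,
            "mae_ma_ca": self.mae_ma_ca,
        }


def _linear_assoc(y, x, covariates):
    """OLS beta of exposure x on outcome y adjusting for covariates."""
    import statsmodels.api as sm

    X = np.c_[np.asarray(x, float), np.asarray(covariates, float)]
    X = sm.add_constant(X)
    fit = sm.OLS(np.asarray(y, float), X).fit()
    b, se = fit.params[1], fit.bse[1]
    return (float(b), float(b - 1.96 * se), float(b + 1.96 * se),
            float(fit.pvalues[1]))


def validate_ma(ma, maa, accelerated, chronological_age, outcomes: dict,
                telomere_z, fi, covariates) -> MAValidationReport:
    """Validation battery: discrimination gain from adding MA to a base
    covariate Cox model, hazard of accelerated aging per endpoint, linear
    associations of acceleration with telomere length and frailty, and
    agreement between MA and chronological age."""
    cov = np.asarray(covariates, float)
    c_base, c_plus, hrs = {}, {}, {}
    for ep, out in outcomes.items():
        t = out["time"].to_numpy(float)
        e = out["event"].to_numpy(float)
        base = fit_cox(t, e, cov)
        c_base[ep] = harrell_c(cov @ base.coef, t, e)
        Xm = np.c_[cov, np.asarray(ma, float)]
        plus = fit_cox(t, e, Xm)
        c_plus[ep] = harrell_c(Xm @ plus.coef, t, e)
        Xa = np.c_[np.asarray(accelerated, float), cov]
        acc_fit = fit_cox(t, e, Xa)
        hrs[ep] = (float(acc_fit.hr[0]), float(acc_fit.ci_low[0]),
                   float(acc_fit.ci_high[0]), float(acc_fit.p[0]))
    beta_tel = _linear_assoc(telomere_z, accelerated, cov)
    beta_fi = _linear_assoc(fi, accelerated, cov)
    rho = float(stats.spearmanr(ma, chronological_age).statistic)
    mae = float(np.mean(np.abs(np.asarray(ma) - np.asarray(chronological_age))))
    return MAValidationReport(
        c_index_base=c_base, c_index_base_plus_ma=c_plus,
        hr_accelerated=hrs, beta_telomere=beta_tel, beta_fi=beta_fi,
        spearman_ma_ca=rho, mae_ma_ca=mae)
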