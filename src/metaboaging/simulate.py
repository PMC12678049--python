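"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* chronological age uniform on a configurable range (default 40-70 years);
* a latent per-participant aging rate ``a ~ N(0, 1)`` shared by the
  metabolome, telomere length (negative loading) and the frailty items
  (positive loading), which is what lets one protein associate with all six
  metabolic-aging phenotypes at once;
* metabolite concentrations loaded on standardised age and on the latent
  rate, stored on a raw positive scale such that the standard
  ``ln(x + 1)`` + z-score preprocessing recovers the latent Gaussian
  exactly;
* mortality (and, independently, incident CVD and T2D) from a Gompertz
  proportional-hazards law on the age timescale, left-truncated at entry
  and administratively censored after a fixed follow-up horizon, with
  event ages drawn by closed-form inversion of the cumulative hazard;
* proteins with planted step-like "waves" at configurable metabolic-age
  centers and three planted trajectory shape families;
* completely-at-random missingness in every matrix.

Every draw flows from a single seed through named ``SeedSequence``
substreams, so cohorts are bit-reproducible and individual blocks do not
shift when unrelated parameters change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_tsv, write_tsv

__all__ = [
    "SimulationConfig", "WaveSpec", "SyntheticCohort", "GroundTruth",
    "generate_cohort", "make_healthy_subset", "write_cohort", "read_cohort",
    "analytic_event_fraction",
]


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration; names the field."""


@dataclass(frozen=True)
class WaveSpec:
    """A planted step in protein expression along true metabolic age."""

    center: float                 # years of metabolic age
    proteins: tuple               # protein column indices
    effect: float = 1.0           # step height, SD of the protein
    width: float = 0.5            # sigmoid transition width, years


def _default_waves():
    # steps planted inside the three trajectory families so that wave
    # proteins also carry the cross-phenotype aging signal
    return (
        WaveSpec(44.0, tuple(range(0, 10))),
        WaveSpec(51.0, tuple(range(20, 30))),
        WaveSpec(63.0, tuple(range(40, 50))),
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the package's reference
    study conditions (a desk-scale stand-in for a biobank cohort)."""

    n_participants: int = 5000
    seed: int = 0
    age_range: tuple = (40.0, 70.0)
    n_metabolites: int = 168
    n_causal_metabolites: int = 18
    n_proteins: int = 200
    gompertz_log_b0: float = float(np.log(1e-5))
    gompertz_gamma: float = 0.09
    causal_betas: tuple = None          # per-SD log-hazard effects
    metabolite_age_loading: float = 0.30
    latent_loading: float = 0.30        # causal metabolites; background 1/4 of it
    followup_years: float = 13.5
    cvd_t2d_hazard_spec: dict = field(default_factory=lambda: {
        "cvd": {"log_b0": float(np.log(4e-5)), "gamma": 0.09, "score_effect": 0.4},
        "t2d": {"log_b0": float(np.log(1.2e-5)), "gamma": 0.09, "score_effect": 0.5},
    })
    wave_spec: tuple = field(default_factory=_default_waves)
    n_aging_proteins: int = 60          # first k proteins carry trajectories
    trajectory_slopes: tuple = (0.03, 0.06)       # SD/year, groups 1 and 3
    trajectory_logistic: tuple = (1.2, 51.0, 2.0)  # amplitude, center, width
    protein_latent_loading: float = 0.35
    protein_noise_sd: float = 0.8
    missingness_rates: dict = field(default_factory=lambda: {
        "metabolites": 0.02, "proteins": 0.05,
        "frailty": 0.02, "covariates": 0.03,
    })
    healthy_subset_fraction: float = 0.6
    n_centers: int = 10
    n_frailty_items: int = 49

    def __post_init__(self):
        for name in ("n_participants", "n_metabolites", "n_causal_metabolites",
                     "n_proteins", "n_centers", "n_frailty_items"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.gompertz_gamma <= 0:
            raise ConfigError("gompertz_gamma must be > 0")
        lo, hi = self.age_range
        if not (30.0 <= lo < hi <= 80.0):
            raise ConfigError("age_range must be an interval within [30, 80]")
        if self.n_causal_metabolites > self.n_metabolites:
            raise ConfigError("n_causal_metabolites exceeds n_metabolites")
        for w in self.wave_spec:
            if not (lo <= w.center <= hi):
                raise ConfigError(f"wave_spec center {w.center} outside age_range")
            if max(w.proteins, default=0) >= self.n_proteins:
                raise ConfigError("wave_spec proteins index out of range")
        for key, r in self.missingness_rates.items():
            if not (0.0 <= r <= 0.3):
                raise ConfigError(f"missingness_rates[{key!r}] must be in [0, 0.3]")
        if not (0.0 <= self.healthy_subset_fraction <= 1.0):
            raise ConfigError("healthy_subset_fraction must be in [0, 1]")
        if self.causal_betas is None:
            mags = np.linspace(0.15, 0.30, self.n_causal_metabolites)
            signs = np.where(np.arange(self.n_causal_metabolites) % 4 == 3, -1.0, 1.0)
            self.causal_betas = tuple(mags * signs)
        if len(self.causal_betas) != self.n_causal_metabolites:
            raise ConfigError("causal_betas length must equal n_causal_metabolites")


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame          # id, age, sex, bmi, deprivation, smoking, center
    metabolites: pd.DataFrame         # raw scale, NaN = missing
    proteins: pd.DataFrame            # NPX-like scale, NaN = missing
    outcomes: dict                    # endpoint -> DataFrame(entry_age, time, event)
    frailty_items: pd.DataFrame       # binary with NaN
    telomere_raw: pd.Series           # positive ratios
    health_flags: pd.DataFrame        # hypertension, dyslipidemia, medication

    @property
    def n(self) -> int:
        return len(self.covariates)


@dataclass
class GroundTruth:
    causal_metabolite_indices: np.ndarray
    true_betas: np.ndarray
    true_gamma: float
    true_latent_rate: np.ndarray
    true_score: np.ndarray
    true_ma: np.ndarray
    wave_centers: np.ndarray
    wave_protein_sets: list
    trajectory_labels: pd.Series      # aging proteins only, values in {1,2,3}
    metabolite_z: pd.DataFrame        # latent standardized metabolites


def _substreams(seed):
    names = ["ages", "latent", "metabolites", "death", "cvd", "t2d",
             "proteins", "frailty", "telomere", "flags", "missing",
             "covariates"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gompertz_exit_age(entry, xb, log_b0, gamma, u):
    """Closed-form inversion of the Gompertz cumulative hazard given entry.

    exp(gamma T) = exp(gamma A) + gamma * (-ln U) / (b0 * exp(xb))
    """
    b = np.exp(log_b0 + xb)
    val = np.exp(gamma * entry) + gamma * (-np.log(u)) / b
    return np.log(val) / gamma


def analytic_event_fraction(entry_ages, log_b0, gamma, horizon):
    """Expected event fraction 1 - exp(-(b0/g)(e^{g(A+h)} - e^{gA})),
    averaged over the given entry ages (null covariate effects)."""
    entry_ages = np.asarray(entry_ages, float)
    b0 = np.exp(log_b0)
    H = (b0 / gamma) * (np.exp(gamma * (entry_ages + horizon))
                        - np.exp(gamma * entry_ages))
    return float(np.mean(1.0 - np.exp(-H)))


def _trajectory_shape(group, ma, cfg):
    """Additive mean shift (SD units) of an aging protein along true MA."""
    mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    if group == 1:
        return cfg.trajectory_slopes[0] * (ma - mid)
    if group == 3:
        return cfg.trajectory_slopes[1] * (ma - mid)
    amp, c, w = cfg.trajectory_logistic
    return amp / (1.0 + np.exp(-(ma - c) / w))


def generate_cohort(config: SimulationConfig):
    """Draw a cohort and its ground truth.  Deterministic given the seed."""
    cfg = config
    n = cfg.n_participants
    rngs = _substreams(cfg.seed)
    lo, hi = cfg.age_range
    age = rngs["ages"].uniform(lo, hi, n)
    age_std = (age - 0.5 * (lo + hi)) / ((hi - lo) / np.sqrt(12.0))
    latent = rngs["latent"].standard_normal(n)

    # --- metabolites ------------------------------------------------------
    m, mc = cfg.n_metabolites, cfg.n_causal_metabolites
    betas = np.asarray(cfg.causal_betas, float)
    w_age = np.full(m, cfg.metabolite_age_loading)
    w_lat = np.full(m, cfg.latent_loading / 4.0)
    sign = np.sign(betas)
    sign[sign == 0] = 1.0
    w_age[:mc] = cfg.metabolite_age_loading * sign
    w_lat[:mc] = cfg.latent_loading * sign
    noise_sd = np.sqrt(np.clip(1.0 - w_age**2 - w_lat**2, 0.05, None))
    z = (np.outer(age_std, w_age) + np.outer(latent, w_lat)
         + rngs["metabolites"].standard_normal((n, m)) * noise_sd)
    met_ids = [f"met{j:03d}" for j in range(m)]
    # raw positive scale; ln(x+1) followed by z-scoring recovers z exactly
    mu = 2.0 + 0.25 * (np.arange(m) % 5)
    raw = np.expm1(np.clip(mu + 0.4 * z, 0.0, None))

    score = z[:, :mc] @ betas
    gamma = cfg.gompertz_gamma
    true_ma = age + score / gamma

    # --- survival outcomes ------------------------------------------------
    outcomes = {}
    specs = {"death": {"log_b0": cfg.gompertz_log_b0, "gamma": gamma,
                       "score_effect": 1.0}}
    for ep, spec in cfg.cvd_t2d_hazard_spec.items():
        specs[ep] = spec
    for ep, spec in specs.items():
        u = rngs[ep if ep in rngs else "death"].uniform(size=n)
        exit_age = _gompertz_exit_age(age, spec["score_effect"] * score,
                                      spec["log_b0"], spec["gamma"], u)
        t = exit_age - age
        event = (t <= cfg.followup_years).astype(int)
        t = np.minimum(t, cfg.followup_years)
        outcomes[ep] = pd.DataFrame(
            {"entry_age": age, "time": t, "event": event})

    # --- proteins ---------------------------------------------------------
    k_aging = min(cfg.n_aging_proteins, cfg.n_proteins)
    groups = np.zeros(cfg.n_proteins, dtype=int)
    per = k_aging // 3
    groups[:per] = 1
    groups[per:2 * per] = 2
    groups[2 * per:k_aging] = 3
    P = rngs["proteins"].standard_normal((n, cfg.n_proteins))
    P[:, :k_aging] *= cfg.protein_noise_sd
    for j in range(k_aging):
        P[:, j] += (_trajectory_shape(groups[j], true_ma, cfg)
                    + cfg.protein_latent_loading * latent)
    for w in cfg.wave_spec:
        step = w.effect / (1.0 + np.exp(-(true_ma - w.center) / w.width))
        for j in w.proteins:
            P[:, j] += step
    prot_ids = [f"prot{j:03d}" for j in range(cfg.n_proteins)]

    # --- frailty, telomere, flags ----------------------------------------
    ni = cfg.n_frailty_items
    offs = np.linspace(-0.5, 0.5, ni)
    logit = -2.2 + 0.6 * age_std[:, None] + 0.5 * latent[:, None] + offs[None, :]
    pfr = 1.0 / (1.0 + np.exp(-logit))
    items = (rngs["frailty"].uniform(size=(n, ni)) < pfr).astype(float)

    tel_lat = (-0.35 * age_std - 0.30 * latent
               + np.sqrt(1 - 0.35**2 - 0.30**2)
               * rngs["telomere"].standard_normal(n))
    telomere_raw = np.exp(0.2 * tel_lat)

    rf = rngs["flags"]
    healthy = rf.uniform(size=n) < cfg.healthy_subset_fraction
    hyp = (rf.uniform(size=n) < 0.6) & ~healthy
    dys = (rf.uniform(size=n) < 0.6) & ~healthy
    med = (rf.uniform(size=n) < 0.5) & ~healthy
    none_set = ~healthy & ~(hyp | dys | med)
    hyp = hyp | none_set   # unhealthy participants carry at least one flag

    rc = rngs["covariates"]
    sex = (rc.uniform(size=n) < 0.45).astype(int)
    bmi = 27.0 + 0.08 * (age - 55.0) + 2.5 * rc.standard_normal(n)
    deprivation = rc.standard_normal(n)
    smoking = (rc.uniform(size=n) < 0.25).astype(int)
    center = rc.integers(0, cfg.n_centers, size=n)

    # --- missingness (MCAR) ----------------------------------------------
    rm = rngs["missing"]
    rates = cfg.missingness_rates
    raw = np.where(rm.uniform(size=raw.shape) < rates.get("metabolites", 0.0),
                   np.nan, raw)
    P = np.where(rm.uniform(size=P.shape) < rates.get("proteins", 0.0),
                 np.nan, P)
    items = np.where(rm.uniform(size=items.shape) < rates.get("frailty", 0.0),
                     np.nan, items)
    # a small fraction of participants get a block of >= 10 missing items so
    # the frailty exclusion rule is exercised
    heavy = rm.uniform(size=n) < 0.01
    for i in np.flatnonzero(heavy):
        cols = rm.choice(ni, size=12, replace=False)
        items[i, cols] = np.nan
    bmi = np.where(rm.uniform(size=n) < rates.get("covariates", 0.0),
                   np.nan, bmi)
    cov_rate2 = min(0.3, 2.0 * rates.get("covariates", 0.0))
    smoking = pd.array(smoking, dtype="Int64")
    smoking[rm.uniform(size=n) < cov_rate2] = pd.NA

    ids = [f"id{i:06d}" for i in range(n)]
    cov = pd.DataFrame({
        "age": age, "sex": sex, "bmi": bmi, "deprivation": deprivation,
        "smoking": smoking, "center": center}, index=pd.Index(ids, name="id"))
    cohort = SyntheticCohort(
        covariates=cov,
        metabolites=pd.DataFrame(raw, index=cov.index, columns=met_ids),
        proteins=pd.DataFrame(P, index=cov.index, columns=prot_ids),
        outcomes={ep: df.set_index(cov.index) for ep, df in outcomes.items()},
        frailty_items=pd.DataFrame(
            items, index=cov.index,
            columns=[f"item{j:02d}" for j in range(ni)]),
        telomere_raw=pd.Series(telomere_raw, index=cov.index, name="telomere"),
        health_flags=pd.DataFrame(
            {"hypertension": hyp.astype(int), "dyslipidemia": dys.astype(int),
             "medication": med.astype(int)}, index=cov.index),
    )
    truth = GroundTruth(
        causal_metabolite_indices=np.arange(mc),
        true_betas=betas.copy(),
        true_gamma=gamma,
        true_latent_rate=latent,
        true_score=score,
        true_ma=true_ma,
        wave_centers=np.array([w.center for w in cfg.wave_spec]),
        wave_protein_sets=[{prot_ids[j] for j in w.proteins}
                           for w in cfg.wave_spec],
        trajectory_labels=pd.Series(groups[:k_aging],
                                    index=prot_ids[:k_aging]),
        metabolite_z=pd.DataFrame(z, index=cov.index, columns=met_ids),
    )
    return cohort, truth


def make_healthy_subset(cohort: SyntheticCohort) -> SyntheticCohort:
    """Rows free of hypertension/dyslipidemia/medication flags."""
    keep = (cohort.health_flags == 0).all(axis=1)
    if not keep.any():
        warnings.warn("healthy subset is empty", RuntimeWarning)
    idx = cohort.covariates.index[keep]
    return SyntheticCohort(
        covariates=cohort.covariates.loc[idx],
        metabolites=cohort.metabolites.loc[idx],
        proteins=cohort.proteins.loc[idx],
        outcomes={ep: df.loc[idx] for ep, df in cohort.outcomes.items()},
        frailty_items=cohort.frailty_items.loc[idx],
        telomere_raw=cohort.telomere_raw.loc[idx],
        health_flags=cohort.health_flags.loc[idx],
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, truth, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.covariates, outdir / "covariates.tsv")
    write_tsv(cohort.metabolites, outdir / "metabolites.tsv")
    write_tsv(cohort.proteins, outdir / "proteins.tsv")
    for ep, df in cohort.outcomes.items():
        write_tsv(df, outdir / f"outcomes_{ep}.tsv")
    write_tsv(cohort.frailty_items, outdir / "frailty_items.tsv")
    write_tsv(cohort.telomere_raw.to_frame(), outdir / "telomere.tsv")
    write_tsv(cohort.health_flags, outdir / "health_flags.tsv")
    if truth is not None:
        payload = {
            "causal_metabolite_indices":
                truth.causal_metabolite_indices.tolist(),
            "true_betas": truth.true_betas.tolist(),
            "true_gamma": truth.true_gamma,
            "wave_centers": truth.wave_centers.tolist(),
            "wave_protein_sets": [sorted(s) for s in truth.wave_protein_sets],
            "trajectory_labels": truth.trajectory_labels.to_dict(),
            "true_ma": [round(float(v), 6) for v in truth.true_ma],
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
    return outdir


def read_cohort(indir) -> SyntheticCohort:
    indir = Path(indir)
    outcomes = {}
    for f in sorted(indir.glob("outcomes_*.tsv")):
        outcomes[f.stem.removeprefix("outcomes_")] = read_tsv(f)
    cov = read_tsv(indir / "covariates.tsv")
    if "smoking" in cov:
        cov["smoking"] = cov["smoking"].astype("Int64")
    return SyntheticCohort(
        covariates=cov,
        metabolites=read_tsv(indir / "metabolites.tsv"),
        proteins=read_tsv(indir / "proteins.tsv"),
        outcomes=outcomes,
        frailty_items=read_tsv(indir / "frailty_items.tsv"),
        telomere_raw=read_tsv(indir / "telomere.tsv")["telomere"],
        health_flags=read_tsv(indir / "health_flags.tsv"),
    )
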