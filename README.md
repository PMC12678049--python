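# metaboaging

A tested, reusable pipeline for studying **metabolic aging** with
metabolomic and proteomic cohort data:

1. build a **metabolic age (MA)** clock from mortality-associated
   metabolomic biomarkers with a Gompertz proportional-hazards model,
2. scan the plasma proteome for associations with six metabolic-aging
   phenotypes (MA, frailty index, telomere length, incident CVD, incident
   T2D, all-cause mortality),
3. detect undulating protein "waves" along MA with a sliding-window
   differential-expression analysis, and
4. cluster MA–protein trajectories and test their monotone trends.

Cohort resources of this kind are access-restricted, so the package ships a
first-class **synthetic-cohort generator** with planted ground truth
(causal metabolites, protein waves, trajectory families) that the test
suite uses for recovery experiments. The analysis code is agnostic about
where its delimited input tables come from.

## The model

Mortality follows a Gompertz proportional-hazards law on the age timescale

    h(t | x) = b · exp(γ t) · exp(xᵀβ),

left-truncated at study entry. A LASSO-penalised Cox model (10-fold CV,
1-SE rule, covariates unpenalised) selects mortality-associated
metabolites; the Gompertz fit on the selected panel yields γ and the
per-participant metabolite score s = xᵀβ (centered). The metabolic age is
the age at which the population-average hazard equals the participant's
predicted hazard at their own chronological age CA:

    b·e^{γ·MA} = b·e^{γ·CA + s}   ⟹   MA = CA + s / γ .

**Metabolic age acceleration (MAA)** is the residual of OLS of MA on CA;
MAA > 0 marks a metabolically older participant. Downstream, per-protein
linear or Cox scans with Bonferroni control are intersected across the six
phenotypes; the DE-SWAN-style wave scan fits, at each MA center c (40…70,
±1.5-year windows),

    protein = α + β₁·1(MA ≥ c) + βₓᵀx + ε

per protein and counts Bonferroni-significant proteins per center — local
maxima of that count curve are the waves. Trajectories are LOESS curves
over MA, clustered with Ward linkage on Euclidean curve distance and
tested with tie-corrected Mann–Kendall statistics. Protein sets are scored
against GMT collections with exact hypergeometric over-representation.

## Worked example

```python
import numpy as np
from scipy import stats
from metaboaging import (SimulationConfig, generate_cohort, MetaboliteMatrix,
                         transform_metabolites, select_ma_metabolites,
                         estimate_metabolic_age)

cfg = SimulationConfig(n_participants=5000, seed=7)
cohort, truth = generate_cohort(cfg)
mets = transform_metabolites(MetaboliteMatrix(cohort.metabolites))
death = cohort.outcomes["death"]
covs = np.c_[cohort.covariates["age"], cohort.covariates["sex"].astype(float)]

sel = select_ma_metabolites(mets.values, death["time"], death["event"],
                            covariates=covs, folds=10, seed=7)
clock = estimate_metabolic_age(mets.values, death["entry_age"],
                               death["time"], death["event"], selection=sel)

print(f"selected metabolites : {len(sel.indices)}")
print(f"gamma (per year)     : {clock.gompertz.gamma:.4f}")
print(f"Spearman r(MA, age)  : "
      f"{stats.spearmanr(clock.ma, cohort.covariates['age']).statistic:.3f}")
print(f"rank corr(MA, true)  : "
      f"{stats.spearmanr(clock.ma, truth.true_ma).statistic:.3f}")
print(f"accelerated fraction : {clock.accelerated.mean():.3f}")
```

Output:

```
selected metabolites : 18
gamma (per year)     : 0.0963
Spearman r(MA, age)  : 0.814
rank corr(MA, true)  : 0.998
accelerated fraction : 0.502
```

The 1-SE LASSO panel recovers exactly the 18 planted mortality metabolites;
the fitted γ is close to the generating value 0.09/year; the estimated MA
rank-correlates 0.998 with the generator's true metabolic age, and about
half the cohort is flagged as accelerated, as the residual definition
implies.

## Command line

```bash
metaboaging run-all --config cfg.yaml --seed 42 --out out/
metaboaging simulate --seed 1 --out out/          # cohort TSVs + truth.json
metaboaging waves --config cfg.yaml --out out/    # one stage + prerequisites
```

Every run writes a `manifest.json` with per-stage summaries and SHA-256
hashes of all outputs; two runs with the same seed are byte-identical.

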