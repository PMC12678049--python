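"""End-to-end orchestration.

simulate -> preprocess -> metabolic age -> proteome-wide scans -> waves ->
trajectories -> enrichment, with a YAML-configurable stage list, a single
root seed feeding named substreams, TSV/JSON outputs and a manifest of
content hashes for reproducibility checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deswan as dsw
from . import enrichment as enr
from . import metabolic_age as mage
from . import preprocess as prep
from . import pwas
from . import trajectories as traj
from .io import sha256_file, write_tsv
from .simulate import (ConfigError, SimulationConfig, generate_cohort,
                       make_healthy_subset, write_cohort)

log = logging.getLogger("metaboaging")

STAGES = ("simulate", "preprocess", "ma", "pwas", "waves", "trajectories",
          "enrich")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "out"
    seed: int = 0
    stages: tuple = STAGES
    alpha: float = 0.05
    split_fraction: float = 0.7
    lasso_folds: int = 10
    k_top: int = 20
    k_clusters: int = 3
    deswan_correction: str = "bonferroni"
    deswan_halfwidth: float = 1.5
    deswan_min_n: int = 30
    # counts of 1-2 significant proteins per center are at the Bonferroni
    # noise level; a peak must clear them (detect_peaks itself defaults to 1)
    peak_min_count: int = 3
    loess_span: float = 0.5
    gmt: str = None

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.deswan_halfwidth <= 0:
            raise ConfigError("deswan_halfwidth must be positive")
        if self.deswan_correction not in ("bonferroni", "fdr"):
            raise ConfigError("deswan_correction must be 'bonferroni' or 'fdr'")
        if self.lasso_folds < 2:
            raise ConfigError("lasso_folds must be >= 2")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")


_NUMERIC = {"seed": int, "alpha": float, "split_fraction": float,
            "lasso_folds": int, "k_top": int, "k_clusters": int,
            "deswan_halfwidth": float, "deswan_min_n": int,
            "peak_min_count": int, "loess_span": float}


def validate_config(source) -> PipelineConfig:
    """Normalize a YAML file or dict into a PipelineConfig with field-level
    error messages."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    allowed = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    sim_raw = raw.pop("simulation", {}) or {}
    if not isinstance(sim_raw, dict):
        raise ConfigError("simulation must be a mapping")
    sim_allowed = {f.name for f in dc_fields(SimulationConfig)}
    sim_unknown = set(sim_raw) - sim_allowed
    if sim_unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(sim_unknown)}")
    for key, caster in _NUMERIC.items():
        if key in raw:
            try:
                raw[key] = caster(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(
                    f"config key {key!r} expects {caster.__name__}, got "
                    f"{raw[key]!r}") from None
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "age_range" in sim_raw:
        sim_raw["age_range"] = tuple(sim_raw["age_range"])
    try:
        sim = SimulationConfig(**sim_raw)
    except TypeError as exc:
        raise ConfigError(f"simulation config: {exc}") from None
    cfg = PipelineConfig(simulation=sim, **raw)
    # one root seed; the simulation inherits it
    cfg.simulation.seed = cfg.seed
    return cfg


def _config_payload(cfg: PipelineConfig) -> dict:
    sim = {f.name: getattr(cfg.simulation, f.name)
           for f in dc_fields(SimulationConfig)}
    sim["wave_spec"] = [[w.center, list(w.proteins), w.effect, w.width]
                        for w in sim["wave_spec"]]
    sim["age_range"] = list(sim["age_range"])
    sim["causal_betas"] = [round(float(b), 10) for b in sim["causal_betas"]]
    sim["trajectory_slopes"] = list(sim["trajectory_slopes"])
    sim["trajectory_logistic"] = list(sim["trajectory_logistic"])
    top = {f.name: getattr(cfg, f.name) for f in dc_fields(PipelineConfig)
           if f.name != "simulation"}
    top["stages"] = list(top["stages"])
    top["simulation"] = sim
    return top


def _split_by_center(centers: pd.Series, fraction: float, seed: int):
    ids = np.sort(centers.unique())
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)
    n_train = max(1, min(len(ids) - 1, int(round(fraction * len(ids)))))
    train_centers = set(order[:n_train].tolist())
    mask = centers.isin(train_centers)
    return mask, train_centers


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest
    (also written to ``out_dir/manifest.json``)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_payload(cfg), "stages": {}, "files": {}}
    produced = []

    def emit(path):
        produced.append(Path(path))

    try:
        ctx = {}
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            log.info("stage %s", stage)
            runner = globals()[f"_stage_{stage}"]
            info = runner(cfg, out, ctx, emit)
            manifest["stages"][stage] = info
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finalize(manifest, produced, out)
        raise
    _finalize(manifest, produced, out)
    return manifest


def _finalize(manifest, produced, out):
    for p in produced:
        manifest["files"][str(p.relative_to(out))] = sha256_file(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate(cfg, out, ctx, emit):
    cohort, truth = generate_cohort(cfg.simulation)
    ctx["cohort"], ctx["truth"] = cohort, truth
    cdir = write_cohort(cohort, truth, out / "cohort")
    for f in sorted(cdir.glob("*")):
        emit(f)
    return {"n_participants": cohort.n,
            "n_metabolites": cohort.metabolites.shape[1],
            "n_proteins": cohort.proteins.shape[1],
            "events": {ep: int(df["event"].sum())
                       for ep, df in cohort.outcomes.items()}}


def _stage_preprocess(cfg, out, ctx, emit):
    cohort = ctx["cohort"]
    met = prep.transform_metabolites(
        prep.MetaboliteMatrix(cohort.metabolites, stage="raw"))
    prot = prep.filter_proteins(
        prep.ProteinMatrix(cohort.proteins, stage="raw"))
    fi = prep.compute_frailty_index(cohort.frailty_items,
                                    n_items=cohort.frailty_items.shape[1])
    tel = prep.prepare_telomere(cohort.telomere_raw)
    imp = prep.impute_covariates(cohort.covariates.drop(columns=["center"]))
    design = prep.encode_design(imp.table)
    ctx.update(metabolites=met, proteins=prot, fi=fi, telomere=tel,
               covariate_design=design, audit=imp.audit)
    mask, train_centers = _split_by_center(
        cohort.covariates["center"], cfg.split_fraction, cfg.seed + 1)
    ctx["train_mask"] = mask
    emit(write_tsv(fi, out / "frailty_index.tsv"))
    (out / "covariate_imputation.json").write_text(
        json.dumps(imp.audit, indent=1, sort_keys=True, default=str))
    emit(out / "covariate_imputation.json")
    return {"n_proteins_kept": prot.values.shape[1],
            "n_proteins_dropped": cohort.proteins.shape[1]
            - prot.values.shape[1],
            "n_frailty_excluded": int(fi["excluded"].sum()),
            "train_centers": sorted(int(c) for c in train_centers),
            "n_train": int(mask.sum()), "n_val": int((~mask).sum())}


def _stage_ma(cfg, out, ctx, emit):
    cohort = ctx["cohort"]
    met = ctx["metabolites"].values
    design = ctx["covariate_design"].to_numpy(float)
    tr = ctx["train_mask"].to_numpy()
    death = cohort.outcomes["death"]
    sel = mage.select_ma_metabolites(
        met.loc[tr], death.loc[tr, "time"], death.loc[tr, "event"],
        covariates=design[tr], folds=cfg.lasso_folds, seed=cfg.seed + 2)
    fit_tr = mage.estimate_metabolic_age(
        met.loc[tr], death.loc[tr, "entry_age"], death.loc[tr, "time"],
        death.loc[tr, "event"], selection=sel)
    result = mage.apply_metabolic_age(met, cohort.covariates["age"], fit_tr)
    ctx["ma_result"] = result
    ctx["ma_selection"] = sel
    frame = result.frame(met.index)
    emit(write_tsv(frame, out / "ma_results.tsv"))

    va = ~tr
    fi_ok = (~ctx["fi"]["fi"].isna()).to_numpy()
    rows = va & fi_ok
    report = mage.validate_ma(
        ma=result.ma[rows], maa=result.maa[rows],
        accelerated=result.accelerated[rows],
        chronological_age=cohort.covariates["age"].to_numpy()[rows],
        outcomes={ep: df.loc[rows] for ep, df in cohort.outcomes.items()},
        telomere_z=ctx["telomere"].to_numpy()[rows],
        fi=ctx["fi"]["fi"].to_numpy()[rows],
        covariates=design[rows])
    ctx["ma_report"] = report
    (out / "validation_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    emit(out / "validation_report.json")
    return {"n_selected_metabolites": int(sel.indices.size),
            "rule_used": sel.rule_used,
            "gamma": round(float(fit_tr.gompertz.gamma), 6),
            "spearman_ma_ca": round(report.spearman_ma_ca, 6),
            "mae_ma_ca": round(report.mae_ma_ca, 6)}


def _phenotype_scans(cfg, cohort, ctx, rows):
    prot = ctx["proteins"].values
    design = ctx["covariate_design"].to_numpy(float)
    result = ctx["ma_result"]
    fi = ctx["fi"]["fi"]
    scans = {}
    for name in ("ma", "fi", "telomere"):
        vals = {"ma": pd.Series(result.ma, index=prot.index),
                "fi": fi, "telomere": ctx["telomere"]}[name]
        ok = rows & vals.notna().to_numpy()
        scans[name] = pwas.scan_proteins(
            prot.loc[ok], pwas.PhenotypeSpec(name, "linear"),
            design[ok], phenotype_values=vals.to_numpy(float)[ok])
    for ep in ("death", "cvd", "t2d"):
        outc = cohort.outcomes[ep]
        scans[ep] = pwas.scan_proteins(
            prot.loc[rows], pwas.PhenotypeSpec(ep, "cox"),
            design[rows], outcome=outc.loc[rows])
    return scans


def _stage_pwas(cfg, out, ctx, emit):
    cohort = ctx["cohort"]
    tr = ctx["train_mask"].to_numpy()
    train_scans = _phenotype_scans(cfg, cohort, ctx, tr)
    val_scans = _phenotype_scans(cfg, cohort, ctx, ~tr)
    inter, counts = pwas.intersect_significant(train_scans, cfg.alpha)
    ctx["intersection"] = inter
    ctx["train_scans"] = train_scans
    for name, s in train_scans.items():
        emit(write_tsv(s.table, out / f"scan_{name}.tsv"))
    emit(write_tsv(counts, out / "intersection.tsv"))
    top = {name: pwas.rank_top(s, cfg.k_top, universe=inter or None)
           for name, s in train_scans.items()}
    (out / "top_proteins.json").write_text(
        json.dumps(top, indent=1, sort_keys=True))
    emit(out / "top_proteins.json")
    conc = {name: pwas.replication_concordance(train_scans[name],
                                               val_scans[name], cfg.alpha)
            for name in train_scans}
    (out / "concordance.json").write_text(
        json.dumps(conc, indent=1, sort_keys=True))
    emit(out / "concordance.json")
    return {"n_intersection": len(inter),
            "n_significant": {k: len(s.significant(cfg.alpha))
                              for k, s in train_scans.items()}}


def _wave_universe(cfg, ctx):
    prot = ctx["proteins"].values
    inter = ctx.get("intersection") or set()
    if len(inter) >= 5:
        return prot[sorted(inter)]
    warnings.warn("intersection too small; waves scan the full proteome",
                  RuntimeWarning)
    return prot


def _stage_waves(cfg, out, ctx, emit):
    cohort = ctx["cohort"]
    healthy = (ctx["cohort"].health_flags == 0).all(axis=1).to_numpy()
    prot = _wave_universe(cfg, ctx).loc[healthy]
    design = ctx["covariate_design"].to_numpy(float)[healthy]
    ma = ctx["ma_result"].ma[healthy]
    grid = dsw.deswan_scan(prot, ma, design,
                           halfwidth=cfg.deswan_halfwidth,
                           correction=cfg.deswan_correction,
                           min_n=cfg.deswan_min_n)
    counts = dsw.count_significant(grid, cfg.alpha)
    peaks = dsw.build_peakset(grid, cfg.alpha, cfg.peak_min_count)
    ctx["deswan"] = grid
    ctx["peaks"] = peaks
    ctx["wave_universe_columns"] = list(prot.columns)
    emit(write_tsv(grid.table.set_index("center"), out / "deswan_grid.tsv"))
    emit(write_tsv(counts.rename("n_significant").to_frame(),
                   out / "deswan_counts.tsv"))
    payload = {"peaks": [float(c) for c in peaks.peak_centers],
               "sets": {str(c): sorted(s)
                        for c, s in peaks.protein_sets.items()}}
    (out / "peaks.json").write_text(json.dumps(payload, indent=1,
                                               sort_keys=True))
    emit(out / "peaks.json")
    return {"n_healthy": int(healthy.sum()),
            "peaks": [float(c) for c in peaks.peak_centers],
            "skipped_centers": [float(c) for c in grid.skipped_centers]}


def _stage_trajectories(cfg, out, ctx, emit):
    healthy = (ctx["cohort"].health_flags == 0).all(axis=1).to_numpy()
    inter = ctx.get("intersection") or set()
    prot = ctx["proteins"].values
    cols = sorted(inter) if len(inter) >= cfg.k_clusters else list(prot.columns)
    ma = ctx["ma_result"].ma[healthy]
    tset = traj.fit_trajectories(prot.loc[healthy, cols], ma,
                                 span=cfg.loess_span)
    tset = traj.assign_trajectory_groups(tset, k=cfg.k_clusters)
    ctx["trajectories"] = tset
    curves = tset.curves.copy()
    curves.columns = [f"ma_{g:g}" for g in tset.grid]
    emit(write_tsv(curves, out / "trajectories.tsv"))
    clust = tset.mk.copy()
    clust.insert(0, "group", tset.labels)
    emit(write_tsv(clust, out / "clusters.tsv"))
    return {"n_proteins": len(cols),
            "group_sizes": tset.labels.value_counts().sort_index()
            .to_dict()}


def _stage_enrich(cfg, out, ctx, emit):
    if not cfg.gmt:
        return {"skipped": "no GMT collection configured"}
    collection = enr.read_gmt(cfg.gmt)
    universe = set(ctx["proteins"].values.columns)
    inter = ctx.get("intersection") or set()
    results = {}
    if inter:
        results["metabolic_aging_set"] = enr.enrich(inter, collection,
                                                    universe)
    tset = ctx.get("trajectories")
    if tset is not None and tset.labels is not None:
        for g in sorted(tset.labels.unique()):
            members = set(tset.labels.index[tset.labels == g])
            if members:
                results[f"trajectory_group_{g}"] = enr.enrich(
                    members, collection, universe)
    if not results:
        return {"skipped": "no nonempty query sets"}
    frames = []
    for name, df in results.items():
        df = df.reset_index()
        df.insert(0, "query", name)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    emit(write_tsv(combined.set_index("query"), out / "enrichment.tsv"))
    return {"queries": sorted(results)}
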