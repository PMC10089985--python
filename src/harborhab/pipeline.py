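"""End-to-end orchestration: simulate -> QC -> presence -> per-species
models -> fit metrics -> interpretation -> community aggregation.

One master seed drives every stage; per-stage and per-species sub-seeds
are derived by hashing stage labels, so per-species model runs are
independent of execution order.  ``run_pipeline`` writes every stage
output as delimited text plus a manifest with row counts, seeds and file
hashes, and returns the in-memory results for programmatic use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .errors import ConfigurationError
from .interpret import (GridSpec, PartialDependence, community_hsi, friedman_h,
                        mda_importance, partial_dependence)
from .metrics import FitMetrics, compute_fit_metrics, confusion_counts
from .model import (DEFAULT_WEIGHT_GRID, ModelConfig, SplitSpec, fit_weighted_rf,
                    predict_presence, split_data, tune_class_weights)
from .presence import build_daily_presence, filter_min_active
from .synthetic import SimConfig, SimStudy, simulate_study, stage_seed, write_study

logger = logging.getLogger("harborhab.pipeline")

TWO_WAY_VARIABLES = ("sav_pct", "depth_m", "exposure_m", "region")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    # QC
    qc_min_span_days: float = 14.0
    qc_min_active_frac: float = 0.5
    # presence table
    min_detections: int = 2
    per_node: bool = True
    n_min_active: int = 5
    # modelling
    species: tuple[str, ...] | None = None   # None = all simulated species
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    model: ModelConfig = field(default_factory=ModelConfig)
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID
    lam: float = 1.0
    tuning_trees: int | None = 250
    calibration_background_n: int = 300
    # interpretation
    pdp_background_n: int = 500
    pdp_points: int = 20
    mda_permutations: int = 5
    h_sample_n: int = 120

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        model = ModelConfig(**raw.pop("model", {}))
        for key in ("species", "weight_grid", "split_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, model=model, **raw)


@dataclass
class SpeciesResult:
    species: str
    model: object
    tuning: object
    split_sizes: tuple[int, int, int]
    metrics: FitMetrics
    pdps: dict[str, PartialDependence]          # one-way, by predictor
    two_way: dict[str, PartialDependence]       # (season, var), by var
    importance: list
    interactions: list


@dataclass
class PipelineResult:
    out_dir: Path
    config: PipelineConfig
    study: SimStudy
    qc: qc_mod.QCResult
    presence: pd.DataFrame
    species_results: dict[str, SpeciesResult]
    fit_metrics: pd.DataFrame
    community: pd.DataFrame
    occupancy_summary: pd.DataFrame
    manifest: dict


def node_occupancy_summary(presence_records: pd.DataFrame) -> pd.DataFrame:
    """Per node x species probability of occurrence: the mean of ``present``
    over the retained node-days."""
    out = (presence_records.groupby(["node_id", "species"], observed=False)["present"]
           .mean().rename("occupancy").reset_index())
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fit_species(records: pd.DataFrame, species: str, config: PipelineConfig,
                seed: int) -> SpeciesResult:
    """Split, tune, fit, evaluate and interpret one species' model."""
    split = SplitSpec(fractions=config.split_fractions,
                      seed=stage_seed(seed, "split", species))
    train, tune, test = split_data(records, split)
    logger.info("%s: split %d/%d/%d (presence rate %.3f)", species,
                len(train), len(tune), len(test), records["present"].mean())

    fit_seed = stage_seed(seed, "fit", species)
    tuning = tune_class_weights(
        train, tune, grid=config.weight_grid, model_config=config.model,
        seed=fit_seed, lam=config.lam, tuning_trees=config.tuning_trees,
        calibration_background_n=config.calibration_background_n)
    final_cfg = replace(config.model, presence_weight=tuning.selected_weight)
    model = fit_weighted_rf(train, final_cfg, seed=fit_seed)

    pred = predict_presence(model, test)
    fm = compute_fit_metrics(confusion_counts(test["present"], pred["pred"]))
    logger.info("%s: weight=%g sens=%.3f spec=%.3f acc=%.3f", species,
                tuning.selected_weight, fm.sensitivity, fm.specificity, fm.accuracy)

    rng = np.random.default_rng(stage_seed(seed, "background", species))
    bg = train if len(train) <= config.pdp_background_n else train.iloc[
        np.sort(rng.choice(len(train), config.pdp_background_n, replace=False))]
    gspec = GridSpec(n_points=config.pdp_points)
    pdps = {v: partial_dependence(model, bg, [v], gspec) for v in model.predictors}
    two_way = {v: partial_dependence(model, bg, ["season", v], gspec)
               for v in TWO_WAY_VARIABLES}
    importance = mda_importance(model, tune, n_permutations=config.mda_permutations,
                                seed=stage_seed(seed, "mda", species))
    interactions = [
        friedman_h(model, bg, "season", v, sample_n=config.h_sample_n,
                   seed=stage_seed(seed, "h", species, v))
        for v in TWO_WAY_VARIABLES]
    return SpeciesResult(species=species, model=model, tuning=tuning,
                         split_sizes=(len(train), len(tune), len(test)),
                         metrics=fm, pdps=pdps, two_way=two_way,
                         importance=importance, interactions=interactions)


def _pdp_long(sp: SpeciesResult) -> pd.DataFrame:
    rows = []
    for pdp in list(sp.pdps.values()) + list(sp.two_way.values()):
        v = pdp.values.copy()
        if len(pdp.variables) == 1:
            rows.append(pd.DataFrame({
                "species": sp.species, "variables": pdp.variables[0],
                "value1": v[pdp.variables[0]], "value2": np.nan, "yhat": v["yhat"]}))
        else:
            rows.append(pd.DataFrame({
                "species": sp.species, "variables": ":".join(pdp.variables),
                "value1": v[pdp.variables[0]], "value2": v[pdp.variables[1]],
                "yhat": v["yhat"]}))
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute every stage and persist all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    logger.info("stage simulate: seed=%d", seed)
    study = simulate_study(config.sim, seed)
    write_study(study, out / "sim")

    logger.info("stage qc: %d raw detections", len(study.detections))
    qc_res = qc_mod.run_qc(study.detections, study.tags,
                           min_span_days=config.qc_min_span_days,
                           min_active_frac=config.qc_min_active_frac)
    qdir = out / "qc"
    qdir.mkdir(exist_ok=True)
    det = qc_res.detections.copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    det.to_csv(qdir / "detections_clean.csv", index=False)
    with open(qdir / "qc_report.json", "w") as fh:
        json.dump(qc_res.report(), fh, indent=1)

    logger.info("stage presence")
    table = build_daily_presence(
        qc_res.detections, study.deployments, study.nodes, study.tags,
        qc_res.windows, min_detections=config.min_detections,
        per_node=config.per_node, season_by_month=config.sim.season_by_month)
    table = filter_min_active(table, config.n_min_active)
    table.to_csv(out / "presence.csv", index=False, date_format="%Y-%m-%d")

    occ_summary = node_occupancy_summary(table)
    occ_summary.to_csv(out / "node_occupancy.csv", index=False)

    species_list = tuple(config.species or config.sim.species)
    unknown = set(species_list) - set(table["species"].unique())
    if unknown:
        raise ConfigurationError(f"no presence rows for species: {sorted(unknown)}")

    results: dict[str, SpeciesResult] = {}
    for sp in species_list:
        records = table[table["species"] == sp].reset_index(drop=True)
        res = fit_species(records, sp, config, seed)
        results[sp] = res
        sdir = out / "species" / sp
        sdir.mkdir(parents=True, exist_ok=True)
        res.tuning.frame().to_csv(sdir / "tuning.csv", index=False)
        _pdp_long(res).to_csv(sdir / "pdp.csv", index=False)
        pd.DataFrame([{"variable": r.variable, "mda": r.mda}
                      for r in res.importance]).to_csv(sdir / "importance.csv", index=False)
        pd.DataFrame([{"pair": ":".join(r.pair), "h": r.h, "sample_n": r.sample_n}
                      for r in res.interactions]).to_csv(sdir / "interactions.csv", index=False)

    fm = pd.DataFrame([{"species": sp, **results[sp].metrics.to_dict()}
                       for sp in species_list]).set_index("species")
    fm.to_csv(out / "fit_metrics.csv")
    fm.round(2).to_csv(out / "fit_metrics_2dp.csv")

    community = community_hsi(
        {sp: {v: r.two_way[v] for v in r.two_way} for sp, r in results.items()})
    community.to_csv(out / "community_hsi.csv", index=False)

    manifest = {
        "seed": seed,
        "species": list(species_list),
        "stage_rows": {
            "detections_raw": int(len(study.detections)),
            "detections_clean": int(len(qc_res.detections)),
            "presence_rows": int(len(table)),
        },
        "qc": qc_res.report(),
        "selected_weights": {sp: results[sp].tuning.selected_weight for sp in species_list},
        "split_sizes": {sp: list(results[sp].split_sizes) for sp in species_list},
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in sorted(out.rglob("*.csv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineResult(out_dir=out, config=config, study=study, qc=qc_res,
                          presence=table, species_results=results, fit_metrics=fm,
                          community=community, occupancy_summary=occ_summary,
                          manifest=manifest)


def config_to_yaml(config: PipelineConfig, path) -> None:
    """Persist a run configuration (round-trips through ``from_yaml``)."""
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
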