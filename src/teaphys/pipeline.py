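"""Config-driven orchestration: simulate -> segment -> indices -> rank ->
sweep -> stats.

Each stage reads only the previous stage's artifacts (CSV/TIFF/PNG/JSON
under ``out_dir``), writes a JSON manifest carrying the config hash and
seed, and is individually re-runnable: deleting a stage directory and
re-running reproduces it from upstream outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices as idx
from . import modeling, ranking, field_stats
from .scene import (Scene, SpectraConfig, TruthModel, generate_scene,
                    generate_physiology, write_mask_png, read_mask_png,
                    ELEVATIONS, FARMING_METHODS)
from .segmentation import SegmentationConfig, segment_canopy

logger = logging.getLogger(__name__)

MONTH_TO_SEASON = {12: "winter", 1: "winter", 2: "winter",
                   3: "spring", 4: "spring", 5: "spring",
                   6: "summer", 7: "summer", 8: "summer",
                   9: "autumn", 10: "autumn", 11: "autumn"}

#: reduced grids for interactive runs; the published grids remain the
#: library default in :mod:`teaphys.modeling`
FAST_GRIDS = {
    "PR": None,
    "PLSR": None,
    "LR": None,
    "RR": None,
    "DTR": [{"max_depth": d, "min_samples_split": s} for d in (4, 10, 25) for s in (5, 20)],
    "RFR": [{"n_estimators": 100, "max_depth": d, "min_samples_split": s}
            for d in (5, 15) for s in (5, 20)],
    "XGBoost": [{"max_depth": d, "learning_rate": lr, "n_estimators": n}
                for d in (3, 6) for lr in (0.05, 0.1) for n in (100, 150)],
    "LightGBM": [{"num_leaves": nl, "learning_rate": lr, "n_estimators": n}
                 for nl in (50, 90) for lr in (0.05, 0.1) for n in (100, 150)],
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_sites: int = 3
    n_dsz_per_site: int = 5
    months: list[int] = field(default_factory=lambda: list(range(1, 13)))
    size_px: int = 96
    canopy_fraction: float = 0.6
    family: str = "MI"
    targets: list[str] = field(default_factory=lambda: ["LAI", "PRI", "PhiPSII"])
    ranking_methods: list[str] = field(default_factory=lambda: ["PCA", "MRMR", "GRA"])
    models: list[str] = field(default_factory=lambda: ["XGBoost"])
    cv_folds: int = 3
    parsimony_fraction: float = 0.95
    max_k: int | None = 10
    grid_preset: str = "fast"  # "fast" | "full"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def model_spec(self, name: str) -> modeling.ModelSpec:
        grid = FAST_GRIDS.get(name) if self.grid_preset == "fast" else None
        return modeling.ModelSpec(name=name, grid=grid, seed=self.seed)


def _write_manifest(path: Path, cfg: RunConfig, stage: str, extra: dict | None = None):
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "manifest.json", "w") as fh:
        json.dump({"stage": stage, "config_hash": cfg.hash(), "seed": cfg.seed,
                   **(extra or {})}, fh, indent=2)


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    """Generate scenes + planted physiology; write TIFFs, truth masks and
    the DSZ metadata table."""
    out = Path(cfg.out_dir) / "scenes"
    out.mkdir(parents=True, exist_ok=True)
    truth = TruthModel.default(seed=cfg.seed)
    truth.to_json(Path(cfg.out_dir) / "truth_model.json")
    rng = np.random.default_rng(cfg.seed)
    rows, feat_rows = [], []
    spectra = SpectraConfig(family=cfg.family)
    scene_id = 0
    for s in range(cfg.n_sites):
        elev = ELEVATIONS[s % 3]
        method = FARMING_METHODS[s % 2]
        for month in cfg.months:
            for d in range(cfg.n_dsz_per_site):
                frac = float(np.clip(cfg.canopy_fraction + rng.normal(0, 0.08), 0.25, 0.9))
                sc = generate_scene(frac, spectra, (cfg.size_px, cfg.size_px),
                                    seed=int(rng.integers(2 ** 31)))
                name = f"scene_{scene_id:04d}"
                sc.to_tiff(out / f"{name}.tif")
                write_mask_png(sc.truth_mask, out / f"{name}_truth.png")
                feats = {}
                for iname in ("NDVI", "GNDVI", "NDRE"):
                    m = idx.compute_index_map(sc, idx.get_index(iname))
                    feats[iname], _ = idx.zonal_mean_index(m, sc.truth_mask)
                feats["CIgreen_n"] = feats["GNDVI"]  # proxy scale for the planted PRI model
                feat_rows.append(feats)
                rows.append({"scene": name, "site_id": f"S{s:02d}",
                             "elevation_class": elev, "farming_method": method,
                             "month": month, "season": MONTH_TO_SEASON[month]})
                scene_id += 1
    meta = pd.DataFrame(rows)
    table = generate_physiology(pd.DataFrame(feat_rows), truth,
                                seed=cfg.seed + 1,
                                metadata=meta[["site_id", "elevation_class",
                                               "farming_method", "season"]])
    table.insert(0, "scene", meta["scene"])
    table["month"] = meta["month"]
    table = table.drop(columns=["NDVI", "GNDVI", "NDRE", "CIgreen_n"])
    table.to_csv(Path(cfg.out_dir) / "dsz_table.csv", index=False)
    _write_manifest(out, cfg, "simulate", {"n_scenes": scene_id})
    return table


def stage_segment(cfg: RunConfig) -> None:
    """Predict canopy masks for every simulated scene."""
    scenes = Path(cfg.out_dir) / "scenes"
    out = Path(cfg.out_dir) / "masks"
    out.mkdir(parents=True, exist_ok=True)
    seg_cfg = SegmentationConfig(seed=cfg.seed)
    n = 0
    for tif in sorted(scenes.glob("scene_*.tif")):
        sc = Scene.from_tiff(tif)
        mask, _, manifest = segment_canopy(sc, seg_cfg, return_details=True)
        write_mask_png(mask, out / f"{tif.stem}_mask.png")
        with open(out / f"{tif.stem}_manifest.json", "w") as fh:
            json.dump(manifest, fh)
        n += 1
    _write_manifest(out, cfg, "segment", {"n_masks": n})


def stage_indices(cfg: RunConfig) -> pd.DataFrame:
    """Zonal index features per DSZ over the predicted masks; appended to
    the DSZ table."""
    base = Path(cfg.out_dir)
    table = pd.read_csv(base / "dsz_table.csv")
    defs = idx.registry_by_family()[cfg.family]
    feat_rows = []
    for name in table["scene"]:
        sc = Scene.from_tiff(base / "scenes" / f"{name}.tif")
        mask = read_mask_png(base / "masks" / f"{name}_mask.png")
        feat_rows.append(idx.compute_feature_vector(sc, mask, defs))
    feats = pd.DataFrame(feat_rows).reset_index(drop=True)
    full = pd.concat([table, feats], axis=1)
    full.to_csv(base / "dsz_features.csv", index=False)
    _write_manifest(base / "features_stage", cfg, "indices",
                    {"n_features": feats.shape[1]})
    return full


def _feature_columns(df: pd.DataFrame, family: str) -> list[str]:
    names = {d.name for d in idx.registry_by_family()[family]}
    return [c for c in df.columns if c in names]


def stage_rank(cfg: RunConfig) -> dict[tuple[str, str], ranking.RankingResult]:
    base = Path(cfg.out_dir)
    df = pd.read_csv(base / "dsz_features.csv")
    cols = _feature_columns(df, cfg.family)
    out = base / "rankings"
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for target in cfg.targets:
        sub = df.dropna(subset=[target] + cols)
        for method in cfg.ranking_methods:
            res = ranking.rank_features(sub[cols], sub[target], method)
            res.table().assign(target=target).to_csv(
                out / f"ranking_{target}_{method}.csv", index=False)
            results[(target, method)] = res
    _write_manifest(out, cfg, "rank")
    return results


def stage_sweep(cfg: RunConfig) -> pd.DataFrame:
    base = Path(cfg.out_dir)
    df = pd.read_csv(base / "dsz_features.csv")
    cols = _feature_columns(df, cfg.family)
    out = base / "sweep"
    out.mkdir(parents=True, exist_ok=True)
    curves = []
    for target in cfg.targets:
        sub = df.dropna(subset=[target] + cols)
        for method in cfg.ranking_methods:
            rank_csv = base / "rankings" / f"ranking_{target}_{method}.csv"
            order = pd.read_csv(rank_csv)["feature"].tolist()
            res = ranking.RankingResult(method, order, dict.fromkeys(order, np.nan))
            scores = pd.read_csv(rank_csv)["score"].tolist()
            res.scores = dict(zip(order, scores))
            for model_name in cfg.models:
                curve = modeling.incremental_sweep(
                    sub[cols], sub[target], res, cfg.model_spec(model_name),
                    cv_folds=cfg.cv_folds, seed=cfg.seed, max_k=cfg.max_k,
                    target=target)
                curve.table().to_csv(
                    out / f"curve_{target}_{method}_{model_name}.csv", index=False)
                curves.append(curve)
    summary = modeling.best_combination(curves)
    summary.to_csv(out / "summary.csv", index=False)
    parsi = summary[["target", "ranking", "model", "best_R2", "threshold",
                     "n_best", "n_reduced", "reduced_R2"]]
    parsi.to_csv(out / "parsimony.csv", index=False)
    _write_manifest(out, cfg, "sweep", {"n_curves": len(curves)})
    return summary


def stage_stats(cfg: RunConfig) -> None:
    base = Path(cfg.out_dir)
    df = pd.read_csv(base / "dsz_features.csv")
    out = base / "stats"
    out.mkdir(parents=True, exist_ok=True)
    field_stats.descriptive_table(df, parameters=cfg.targets).to_csv(
        out / "descriptive.csv", index=False)
    sig_rows = []
    for target in cfg.targets:
        for elev in sorted(df["elevation_class"].unique()):
            try:
                c = field_stats.compare_farming_methods(df, target, elev)
                sig_rows.append({"target": target, "grouping": c.grouping, "test": c.test,
                                 "levene_p": c.levene_p, "p": c.p_value,
                                 "significant": c.significant, "letters": ""})
            except ValueError:
                pass
        for method in sorted(df["farming_method"].unique()):
            try:
                c = field_stats.compare_elevations(df, target, method)
                sig_rows.append({"target": target, "grouping": c.grouping, "test": c.test,
                                 "levene_p": c.levene_p, "p": c.p_value,
                                 "significant": c.significant,
                                 "letters": json.dumps(c.letters)})
            except ValueError:
                pass
    pd.DataFrame(sig_rows).to_csv(out / "significance.csv", index=False)
    # grouped residual report for the first target/model via CV predictions
    cols = _feature_columns(df, cfg.family)
    target = cfg.targets[0]
    sub = df.dropna(subset=[target] + cols).reset_index(drop=True)
    from sklearn.model_selection import KFold

    spec = cfg.model_spec(cfg.models[0])
    fit = modeling.fit_model(sub[cols], sub[target], spec, cv_folds=cfg.cv_folds,
                             seed=cfg.seed)
    pred = np.empty(len(sub))
    for tr, va in KFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed).split(sub):
        est = modeling.make_estimator(spec.name, fit.best_params, cfg.seed)
        est.fit(sub.loc[tr, cols], sub.loc[tr, target])
        pred[va] = np.asarray(est.predict(sub.loc[va, cols])).reshape(-1)
    resid = sub[["elevation_class", "season", "farming_method"]].copy()
    resid["residual"] = pred - sub[target]
    field_stats.grouped_error_report(resid).to_csv(out / "grouped_error.csv", index=False)
    _write_manifest(out, cfg, "stats")


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "indices": stage_indices,
    "rank": stage_rank,
    "sweep": stage_sweep,
    "stats": stage_stats,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None):
    """Run the requested stages in workflow order, halting with a
    stage-named error on failure (partial outputs are retained)."""
    for name in stages or list(STAGES):
        logger.info("running stage %s", name)
        try:
            STAGES[name](cfg)
        except Exception as exc:
            raise StageError(name, exc) from exc
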