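"""End-to-end pipeline: simulate/load -> cross-validate -> retrain -> screen
-> saliency patterns -> ROI statistics -> correlations & mediation ->
per-stratum accuracy.

Every stage logs its wall time and seeds; every artifact is re-derivable
from the config plus seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .model import ModelConfig, SexNet, cohort_predictors, crossvalidate, fit_full, subject_scores
from .saliency import cohort_pattern, roi_statistics, saliency_maps, screen_predictors, threshold_pattern
from .stats import partial_mediation, per_stratum_accuracy, score_correlations
from .synthetic import generate_cognitive_scores, generate_cohort
from .types import EffectSpec, SyntheticCohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("sexnet")


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 120
    grid: int = 16
    noise_sd: float = 1.0
    effects: tuple[EffectSpec, ...] = (
        EffectSpec(region_label=1, effect_kind="intensity_shift", driver="sex", magnitude=3.0),
    )
    mediation_link: dict = field(default_factory=lambda: {"list_sorting": 3.0})


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; all randomness flows from ``seed``."""

    outdir: str = "results/run"
    seed: int = 0
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    volumes_dir: str | None = None
    cohort_csv: str | None = None
    atlas_path: str | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    cv_folds: int = 5
    cv_runs: int = 1
    screening_alpha: float = 0.05
    saliency_threshold: float = 0.1
    mediation_n_perm: int = 2000
    min_per_sex: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            syn["effects"] = tuple(EffectSpec(**e) for e in syn.get("effects", []))
            raw["synthetic"] = SyntheticConfig(**syn)
        if "model" in raw:
            model = dict(raw["model"])
            for key in ("conv_channels", "hidden"):
                if key in model:
                    model[key] = tuple(model[key])
            raw["model"] = ModelConfig(**model)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("volumes_dir", "cohort_csv", "atlas_path"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"real-data run requires {name}")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{name} does not exist: {value}")
        if not 0 < self.screening_alpha < 1:
            raise ValueError("screening_alpha must lie in (0, 1)")
        if not 0 <= self.saliency_threshold <= 1:
            raise ValueError("saliency_threshold must lie in [0, 1]")

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(cfg: RunConfig) -> SyntheticCohort:
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        cohort = generate_cohort(
            n=syn.n,
            grid=syn.grid,
            effects=list(syn.effects),
            noise_sd=syn.noise_sd,
            seed=cfg.seed,
        )
        cohort.records = generate_cognitive_scores(
            cohort.records, mediation_link=syn.mediation_link, seed=cfg.seed + 1
        )
        return cohort
    records = sio.read_cohort(cfg.cohort_csv)
    volumes, spacing = sio.load_volumes(cfg.volumes_dir, list(records["subject_id"]))
    atlas = sio.load_atlas(cfg.atlas_path)
    return SyntheticCohort(
        records=records, volumes=volumes, atlas=atlas, truth=[], seed=cfg.seed, spacing=spacing
    )


class _Stage:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.1fs", self.name, dt)
            return False
        log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; artifacts land in ``cfg.outdir``.

    A stage failure halts the run (already-written artifacts persist) and
    names the stage.  Returns the output directory.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)

    with _Stage("load"):
        cohort = _load_cohort(cfg)
        if model_cfg.grid != cohort.grid:
            model_cfg = dataclasses.replace(model_cfg, grid=cohort.grid)
        cohort.records.to_csv(out / "cohort.csv", index=False)

    with _Stage("crossvalidate"):
        pred, report = crossvalidate(cohort, k=cfg.cv_folds, cfg=model_cfg, seed=cfg.seed)
        pred = pred.merge(
            cohort.records[["subject_id", "pds_level"]], on="subject_id", how="left"
        )
        pred.to_csv(out / "predictions.csv", index=False)
        pd.DataFrame([dataclasses.asdict(report)]).to_csv(out / "metrics.csv", index=False)

    with _Stage("retrain_full"):
        model = fit_full(cohort, model_cfg)
        full_scores = subject_scores(model, cohort.volumes)["score"].to_numpy()

    with _Stage("screen"):
        p_matrix = cohort_predictors(model, cohort.volumes)
        screen = screen_predictors(
            p_matrix, full_scores, cohort.records, alpha=cfg.screening_alpha
        )
        screen.to_frame().to_csv(out / "screen.csv", index=True)

    with _Stage("saliency_patterns"):
        free = cohort_pattern(model, cohort.volumes, screen, mode="confounder_free")
        sio.save_volume(free.data, out / "pattern_confounder_free.nii.gz", cohort.spacing)
        sio.save_volume(
            threshold_pattern(free, cfg.saliency_threshold).astype(np.uint8),
            out / "pattern_confounder_free_mask.nii.gz",
            cohort.spacing,
        )
        if screen.confounded_mask.any():
            conf = cohort_pattern(model, cohort.volumes, screen, mode="confounded")
            sio.save_volume(conf.data, out / "pattern_confounded.nii.gz", cohort.spacing)

    with _Stage("roi_statistics"):
        maps = saliency_maps(model, cohort.volumes, screen.free_mask)
        roi = roi_statistics(maps, cohort.atlas, cohort.records["sex"].to_numpy())
        roi.to_csv(out / "roi_saliency.csv", index=False)

    with _Stage("correlations_mediation"):
        nih_cols = [c for c in cohort.records.columns if c.startswith("nih_")]
        if nih_cols:
            cv_scores = pred.set_index("subject_id").loc[
                cohort.records["subject_id"], "score"
            ].to_numpy()
            corr = score_correlations(cv_scores, cohort.records[nih_cols])
            corr.to_csv(out / "correlations.csv", index=False)
            med_rows = []
            sex = cohort.records["sex"].to_numpy()
            for col in nih_cols:
                res = partial_mediation(
                    sex,
                    cv_scores,
                    cohort.records[col].to_numpy(),
                    n_perm=cfg.mediation_n_perm,
                    seed=cfg.seed + 2,
                )
                med_rows.append({"test": col, **dataclasses.asdict(res)})
            pd.DataFrame(med_rows).to_csv(out / "mediation.csv", index=False)

    with _Stage("stratum_accuracy"):
        strat = per_stratum_accuracy(pred, stratum="pds_level", min_per_sex=cfg.min_per_sex)
        strat.to_csv(out / "stratum_accuracy.csv", index=False)

    (out / "run_info.json").write_text(
        json.dumps({"config_digest": cfg.digest(), "seed": cfg.seed}, indent=2)
    )
    return out
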