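"""End-to-end study orchestration.

Runs the whole modelling study at desk scale: synthesize (or load) the
replicate dataset, screen for outliers, and for each modelled response fit
and compare the GA-selected network against the stepwise-regression baseline
under one shared cross-validation plan, then rank the inputs by
leave-variable-out sensitivity. Emits CSV report tables (fit statistics,
sensitivity, predicted-vs-observed pairs, GA convergence) plus a JSON run
log; every file carries the configuration hash and seed, and identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    MODELED_RESPONSES,
    Dataset,
    load_substrate_summary,
    read_dataset,
    resolve_response,
    write_dataset,
)
from .errors import ConfigurationError
from .ga import GAConfig, optimize_architecture
from .mlp import TrainConfig
from .preprocess import make_cv_plan, pca_outlier_screen
from .sensitivity import variable_sensitivity
from .stepwise import sr_crossval
from .synth import GeneratorConfig, generate_replicates

logger = logging.getLogger("fungicast")

_DEFAULT_RESPONSES = tuple(r.name for r in MODELED_RESPONSES)


@dataclass
class StudyConfig:
    """Fully serializable description of one study run."""

    source: str = "fixture"  # "fixture" or a replicate-CSV path
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cv_seed: int = 43
    cv_k: int = 5
    cv_replicates: int = 10
    ga: GAConfig = field(default_factory=GAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sensitivity_mode: str = "retrain"
    boxcox_mode: str = "global"  # "global" | "per_fold" | "none"
    responses: tuple[str, ...] = _DEFAULT_RESPONSES
    search_replicates: int = 1
    paper_faithful: bool = False
    outdir: str = "fungicast_run"

    def __post_init__(self):
        for r in self.responses:
            resolve_response(r)
        if self.sensitivity_mode not in ("retrain", "ablate"):
            raise ConfigurationError(f"unknown sensitivity mode {self.sensitivity_mode!r}")
        if self.boxcox_mode not in ("global", "per_fold", "none"):
            raise ConfigurationError(f"unknown boxcox mode {self.boxcox_mode!r}")

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "StudyConfig":
        """Derive all stage seeds from one base seed (kept below 2^31)."""
        base = int(seed) % (2**31 - 5)
        gen = overrides.pop("generator", GeneratorConfig(seed=base))
        ga = overrides.pop("ga", GAConfig(seed=base + 2))
        train = overrides.pop("train", TrainConfig(seed=base + 3))
        return cls(generator=gen, cv_seed=base + 1, ga=ga, train=train, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # run placement, not part of the science
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        if "generator" in raw and isinstance(raw["generator"], dict):
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if "ga" in raw and isinstance(raw["ga"], dict):
            raw["ga"] = GAConfig(**raw["ga"])
        if "train" in raw and isinstance(raw["train"], dict):
            raw["train"] = TrainConfig(**raw["train"])
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def load_study_dataset(cfg: StudyConfig) -> Dataset:
    if cfg.source == "fixture":
        return generate_replicates(load_substrate_summary(), cfg.generator)
    return read_dataset(cfg.source)


def run_full_study(cfg: StudyConfig) -> dict:
    """Execute generate → screen → per-response (architecture search, CV
    comparison, sensitivity) and write the report bundle to ``cfg.outdir``.

    Returns a dict with the in-memory results and output paths.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={cfg.config_hash} seed={cfg.generator.seed}"
    ga_cfg = cfg.ga.paper_faithful() if cfg.paper_faithful else cfg.ga
    boxcox = None if cfg.boxcox_mode == "none" else cfg.boxcox_mode

    stage = "generate"
    try:
        dataset = load_study_dataset(cfg)
        write_dataset(
            dataset,
            outdir / "dataset.csv",
            check_ordering=cfg.generator.enforce_ordering,
        )

        stage = "screen"
        screen_vars = [resolve_response(r).column for r in cfg.responses]
        flags, distances = pca_outlier_screen(dataset.frame.loc[:, screen_vars].to_numpy(float))
        (outdir / "screen.json").write_text(
            json.dumps(
                {
                    "config_hash": cfg.config_hash,
                    "n_flagged": int(flags.sum()),
                    "flagged_records": np.where(flags)[0].tolist(),
                    "max_score_distance": float(distances.max()),
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        logger.info("outlier screen: %d/%d records flagged", int(flags.sum()), len(flags))

        stage = "cv-plan"
        plan = make_cv_plan(
            len(dataset), cfg.cv_seed, k=cfg.cv_k, n_replicates=cfg.cv_replicates
        )

        fit_rows, sens_frames, ga_rows, pred_frames, stab_frames = [], [], [], [], []
        searches = {}
        for resp_name in cfg.responses:
            stage = f"fit:{resp_name}"
            logger.info("response %s: architecture search", resp_name)
            search = optimize_architecture(
                dataset,
                resp_name,
                plan,
                ga_cfg,
                cfg.train,
                boxcox=boxcox,
                search_replicates=cfg.search_replicates,
            )
            searches[resp_name] = search
            fit_rows.append(search.report.to_row())
            hist = search.ga_result.history.copy()
            hist.insert(0, "response", resp_name)
            ga_rows.append(hist)
            mlp_pred = search.report.predictions.copy()
            mlp_pred.insert(0, "model", "MLP-GA")
            mlp_pred.insert(0, "response", resp_name)
            pred_frames.append(mlp_pred)

            stage = f"sr:{resp_name}"
            sr_report, stability = sr_crossval(dataset, resp_name, plan, boxcox=boxcox)
            assert sr_report.plan_hash == search.report.plan_hash
            fit_rows.append(sr_report.to_row())
            stability.insert(0, "response", resp_name)
            stab_frames.append(stability)
            sr_pred = sr_report.predictions.copy()
            sr_pred.insert(0, "model", "SR")
            sr_pred.insert(0, "response", resp_name)
            pred_frames.append(sr_pred)

            stage = f"sensitivity:{resp_name}"
            sens = variable_sensitivity(
                dataset,
                resp_name,
                search.hidden_n,
                cfg.train,
                mode=cfg.sensitivity_mode,
                boxcox=boxcox,
            )
            if sens.unstable:
                logger.warning(
                    "response %s: VSR spread is small; rescaled ranking unstable",
                    resp_name,
                )
            sens_frames.append(sens.frame)

        stage = "report"
        table4 = pd.DataFrame(fit_rows)
        table5 = pd.concat(sens_frames, ignore_index=True)
        preds = pd.concat(pred_frames, ignore_index=True)
        ga_hist = pd.concat(ga_rows, ignore_index=True)
        stability = pd.concat(stab_frames, ignore_index=True)
        _write_csv(table4, outdir / "table4_analogue.csv", tag)
        _write_csv(table5, outdir / "table5_analogue.csv", tag)
        _write_csv(preds, outdir / "predicted_vs_observed.csv", tag)
        _write_csv(ga_hist, outdir / "ga_history.csv", tag)
        _write_csv(stability, outdir / "sr_selection_stability.csv", tag)
        (outdir / "cv_plan.json").write_text(plan.to_json(), encoding="utf-8")
        run_log = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash,
            "plan_hash": plan.plan_hash,
            "seeds": {
                "generator": cfg.generator.seed,
                "cv": cfg.cv_seed,
                "ga": ga_cfg.seed,
                "train": cfg.train.seed,
            },
            "selected_hidden_n": {r: searches[r].hidden_n for r in cfg.responses},
            "elapsed_s": round(time.time() - t0, 3),
        }
        (outdir / "run_log.json").write_text(
            json.dumps(run_log, indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )
    except Exception as exc:
        logger.error("study aborted in stage %r: %s", stage, exc)
        exc.add_note(f"study stage: {stage}; partial outputs kept in {outdir}")
        raise

    return {
        "outdir": outdir,
        "dataset": dataset,
        "plan": plan,
        "table4": table4,
        "table5": table5,
        "searches": searches,
        "config_hash": cfg.config_hash,
    }
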