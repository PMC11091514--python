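"""End-to-end orchestration: simulate -> replay -> train -> evaluate -> drift.

One config dict (usually loaded from YAML) drives every stage; a
:class:`RunManifest` records seeds, per-stage wall times and a SHA-256
digest of every artifact, so a rerun with the same config is verifiably
identical for the deterministic stages.  Stages whose outputs already exist
in the output directory are skipped, which makes interrupted runs
resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as ortio
from .config import ModelSpec, SimConfig
from .errors import ConfigError, DataError
from .models import BaselineDurationRegressor, DurationModel, fit_baseline, train_model
from .replay import Vocabulary, build_vocab, load_snapshots, persist_snapshots, snapshot_stream
from .scoring import STRATIFIERS, aggregate, score_predictions, summarize
from .simulate import apply_operating_window, build_operating_window, generate_cases, generate_streams, inject_latency
from .drift import drift

log = logging.getLogger("ortime")

STAGES = ("simulate", "replay", "train", "evaluate", "drift")


@dataclass
class RunManifest:
    config_digest: str
    seeds: dict
    package_version: str
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict, elapsed: float) -> None:
        self.stages[stage] = {
            "completed_at": pd.Timestamp.now().isoformat(),
            "elapsed_s": round(elapsed, 3),
        }
        self.artifacts.update(outputs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "seeds": self.seeds,
                "package_version": self.package_version,
                "stages": self.stages,
                "artifacts": self.artifacts,
            },
            indent=2,
            sort_keys=True,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def default_config() -> dict:
    """A small, fast demonstration configuration."""
    return {
        "simulate": {"n_days": 42, "cases_per_weekday": 18, "seed": 0},
        "replay": {"min_count": 2, "lookback": 120.0},
        "split": {"train_end": "2023-01-16"},
        "model": {"epochs": 4, "seed": 0},
        "evaluate": {"stratify": list(STRATIFIERS), "min_n": 1},
    }


def run_all(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full pipeline, writing artifacts and a manifest.

    ``seed``, when given, overrides both the generator and the model seed.
    Raises :class:`ConfigError` for malformed configuration and
    :class:`DataError` for inconsistent data; any stage failure names the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {**default_config(), **(config or {})}
    sim_cfg = SimConfig.from_dict(config.get("simulate", {}))
    spec = ModelSpec.from_dict(config.get("model", {}))
    if seed is not None:
        sim_cfg.seed = int(seed)
        spec.seed = int(seed)
    sim_cfg.validate()
    spec.validate()
    replay_cfg = config.get("replay", {})
    min_count = int(replay_cfg.get("min_count", 2))
    lookback = float(replay_cfg.get("lookback", 120.0))
    split_cfg = config.get("split", {})
    if "train_end" not in split_cfg:
        raise ConfigError("split.train_end is required")
    train_end = pd.Timestamp(split_cfg["train_end"])

    manifest = RunManifest(
        config_digest=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        seeds={"simulate": sim_cfg.seed, "model": spec.seed},
        package_version=_version(),
    )

    paths = {
        "cases": out / "cases.csv",
        "observations": out / "observations.jsonl",
        "capture_log": out / "capture_log.json",
        "vocab": out / "vocab.json",
        "snapshots_train": out / "snapshots_train.jsonl",
        "model": out / "model.npz",
        "baseline": out / "baseline.json",
        "scores": out / "scores.csv",
        "summary": out / "summary.json",
        "drift_weekly": out / "drift.csv",
        "drift_summary": out / "drift_summary.json",
    }

    def stage_done(*keys) -> bool:
        return all(paths[k].exists() for k in keys)

    def finish(stage: str, t0: float, *keys) -> None:
        manifest.record(
            stage, {k: _digest(paths[k]) for k in keys}, time.time() - t0
        )
        (out / "manifest.json").write_text(manifest.to_json())

    # ---- simulate ---------------------------------------------------- #
    t0 = time.time()
    if not stage_done("cases", "observations", "capture_log"):
        _run_stage("simulate", lambda: _simulate_stage(sim_cfg, paths))
    finish("simulate", t0, "cases", "observations", "capture_log")
    cases = ortio.read_cases(paths["cases"])
    observations = ortio.read_observations(paths["observations"])
    window = build_operating_window(sim_cfg)
    train_cases = cases[cases["anaesthesia_start"] < train_end]
    test_cases = cases[cases["anaesthesia_start"] >= train_end]
    if len(train_cases) < 2 or len(test_cases) < 1:
        raise DataError(
            f"split.train_end={train_end.date()} leaves "
            f"{len(train_cases)} train / {len(test_cases)} test cases"
        )
    log.info("simulate: %d captured cases (%d train / %d test), %d observations",
             len(cases), len(train_cases), len(test_cases), len(observations))

    # ---- replay ------------------------------------------------------ #
    t0 = time.time()
    if not stage_done("vocab", "snapshots_train"):
        def _replay():
            train_obs = observations[
                observations["case_id"].isin(set(train_cases["case_id"]))
            ]
            vocab = build_vocab(train_cases, train_obs, min_count=min_count)
            paths["vocab"].write_text(vocab.to_json())
            n = persist_snapshots(
                snapshot_stream(train_cases, train_obs, vocab,
                                window=window, lookback=lookback),
                paths["snapshots_train"],
            )
            log.info("replay: %d training snapshots", n)
        _run_stage("replay", _replay)
    finish("replay", t0, "vocab", "snapshots_train")
    vocab = Vocabulary.from_json(paths["vocab"].read_text())

    # ---- train ------------------------------------------------------- #
    t0 = time.time()
    if not stage_done("model", "baseline"):
        def _train():
            model = train_model(load_snapshots(paths["snapshots_train"]), spec, vocab)
            model.save(paths["model"])
            baseline = fit_baseline(train_cases)
            paths["baseline"].write_text(json.dumps(baseline.to_dict(), indent=2))
            log.info("train: baseline slope %.3f intercept %.2f",
                     baseline.slope_, baseline.intercept_)
        _run_stage("train", _train)
    finish("train", t0, "model", "baseline")

    # ---- evaluate ---------------------------------------------------- #
    t0 = time.time()
    if not stage_done("scores", "summary"):
        def _evaluate():
            model = DurationModel.load(paths["model"], vocab)
            baseline = BaselineDurationRegressor.from_dict(
                json.loads(paths["baseline"].read_text())
            )
            test_obs = observations[
                observations["case_id"].isin(set(test_cases["case_id"]))
            ]
            preds = model.predict_batch(
                snapshot_stream(test_cases, test_obs, vocab,
                                window=window, lookback=lookback)
            )
            scores = score_predictions(preds, test_cases, baseline)
            ortio.write_scores(scores, paths["scores"])
            summary = summarize(scores)
            paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
            eval_cfg = config.get("evaluate", {})
            for by in eval_cfg.get("stratify", []):
                agg = aggregate(scores, by, min_n=int(eval_cfg.get("min_n", 1)))
                agg.to_csv(out / f"aggregate_{by}.csv", index=False,
                           float_format="%.6f")
            log.info("evaluate: %d predictions, model CRPS %.2f vs baseline %.2f",
                     summary["n_predictions"], summary["mean_crps_model"],
                     summary["mean_crps_baseline"])
        _run_stage("evaluate", _evaluate)
    finish("evaluate", t0, "scores", "summary")

    # ---- drift ------------------------------------------------------- #
    t0 = time.time()
    if not stage_done("drift_weekly", "drift_summary"):
        def _drift():
            scores = ortio.read_scores(paths["scores"])
            res = drift(scores)
            res.weekly.to_csv(paths["drift_weekly"], index=False,
                              float_format="%.6f")
            paths["drift_summary"].write_text(json.dumps(
                {
                    "slope_per_week": res.slope,
                    "slope_ci95": list(res.slope_ci),
                    "intercept": res.intercept,
                    "n_weeks": res.n_weeks,
                },
                indent=2, sort_keys=True,
            ))
            log.info("drift: slope %.5f/week over %d weeks", res.slope, res.n_weeks)
        _run_stage("drift", _drift)
    finish("drift", t0, "drift_weekly", "drift_summary")
    return manifest


def _simulate_stage(sim_cfg: SimConfig, paths: dict) -> None:
    cases = generate_cases(sim_cfg)
    obs = generate_streams(cases, sim_cfg)
    obs = inject_latency(obs, sim_cfg)
    kept_cases, kept_obs, capture_log = apply_operating_window(obs, cases, sim_cfg)
    ortio.write_cases(kept_cases, paths["cases"])
    ortio.write_observations(kept_obs, paths["observations"])
    paths["capture_log"].write_text(json.dumps(
        {k: v for k, v in capture_log.items()
         if k not in ("window", "in_window_minutes")},
        indent=2, sort_keys=True,
    ))


def _run_stage(name: str, fn) -> None:
    try:
        fn()
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # surface which stage died
        raise DataError(f"stage '{name}' failed: {exc}") from exc


def _version() -> str:
    from . import __version__

    return __version__
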