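"""Shared fixtures.

Two tiers of synthetic data:

* ``medium_sim`` (module-independent, session scope) — a few hundred cases,
  enough for empirical checks of the generator's statistical structure.
* ``study`` (session scope) — the desk-scale study: ~2000 captured training
  cases and ~1000 captured test cases, a trained duration network, the
  fitted benchmark and the full score table.  Built once because training
  is the expensive step; every test that needs a trained model shares it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from ortime import (
    ModelSpec,
    SimConfig,
    build_vocab,
    fit_baseline,
    simulate,
    snapshot_stream,
    train_model,
)
from ortime.scoring import score_predictions


@pytest.fixture(scope="session")
def medium_sim():
    """~900 generated cases with streams, latency and window censoring."""
    cfg = SimConfig(n_days=45, cases_per_weekday=60, seed=11)
    cases, obs, log = simulate(cfg)
    return cfg, cases, obs, log


@dataclass
class Study:
    config: SimConfig
    spec: ModelSpec
    train_cases: pd.DataFrame
    test_cases: pd.DataFrame
    train_obs: pd.DataFrame
    test_obs: pd.DataFrame
    vocab: object
    window: object
    model: object
    baseline: object
    scores: pd.DataFrame
    capture_log: dict


STUDY_SEED = 101
STUDY_SPLIT = pd.Timestamp("2023-03-06")  # nine training weeks, five test weeks


@pytest.fixture(scope="session")
def study() -> Study:
    cfg = SimConfig(n_days=98, cases_per_weekday=55, seed=STUDY_SEED)
    cases, obs, log = simulate(cfg)
    is_train = cases["anaesthesia_start"] < STUDY_SPLIT
    train_cases = cases[is_train].reset_index(drop=True)
    test_cases = cases[~is_train].reset_index(drop=True)
    train_ids = set(train_cases["case_id"])
    train_obs = obs[obs["case_id"].isin(train_ids)].reset_index(drop=True)
    test_obs = obs[~obs["case_id"].isin(train_ids)].reset_index(drop=True)

    vocab = build_vocab(train_cases, train_obs, min_count=2)
    spec = ModelSpec(seed=7)
    window = log["window"]
    model = train_model(
        snapshot_stream(train_cases, train_obs, vocab, window=window),
        spec, vocab,
    )
    baseline = fit_baseline(train_cases)
    preds = model.predict_batch(
        snapshot_stream(test_cases, test_obs, vocab, window=window)
    )
    scores = score_predictions(preds, test_cases, baseline)
    return Study(
        config=cfg, spec=spec,
        train_cases=train_cases, test_cases=test_cases,
        train_obs=train_obs, test_obs=test_obs,
        vocab=vocab, window=window, model=model, baseline=baseline,
        scores=scores, capture_log=log,
    )


def make_case(case_id="C000001", start="2023-01-04 09:00:00", duration=60.0,
              scheduled=60.0, hospital="academic_adult", service="general surgery",
              location="OR-01", urgency="elective", procedure="left knee repair"):
    """One handcrafted case row (helper used across test modules)."""
    start = pd.Timestamp(start)
    return pd.DataFrame([{
        "case_id": case_id,
        "hospital": hospital,
        "location": location,
        "service": service,
        "urgency": urgency,
        "procedure_name": procedure,
        "scheduled_start": start,
        "scheduled_end": start + pd.Timedelta(minutes=scheduled),
        "scheduled_duration": float(scheduled),
        "anaesthesia_start": start,
        "anaesthesia_stop": start + pd.Timedelta(minutes=duration),
        "actual_duration": float(duration),
    }])


def make_obs(case_id, rows, start="2023-01-04 09:00:00"):
    """Observation frame from (stream, name, action, value, charted_min,
    ingest_min) tuples with offsets in minutes from ``start``."""
    start = pd.Timestamp(start)
    recs = []
    for stream, name, action, value, charted, ingest in rows:
        recs.append({
            "case_id": case_id,
            "stream": stream,
            "name": name,
            "action": action,
            "value": value,
            "charted_time": start + pd.Timedelta(minutes=charted),
            "ingest_time": (start + pd.Timedelta(minutes=ingest)
                            if ingest is not None else pd.NaT),
        })
    return pd.DataFrame(recs)
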