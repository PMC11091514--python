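"""Readers/writers for the on-disk formats.

cases.csv — one row per case, ISO-8601 datetimes, header required.
observations.jsonl — one observation per line with keys exactly
``case_id, stream, name, action, value, charted_time, ingest_time``.
scores.csv / aggregates.csv — plain CSV.  All writers are deterministic
(fixed column order, fixed float formatting), so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import CASE_COLUMNS, OBS_COLUMNS

_DATETIME_CASE_COLS = ("scheduled_start", "scheduled_end",
                       "anaesthesia_start", "anaesthesia_stop")


def write_cases(cases: pd.DataFrame, path) -> None:
    out = cases[CASE_COLUMNS].copy()
    for col in _DATETIME_CASE_COLS:
        out[col] = pd.DatetimeIndex(out[col]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def read_cases(path) -> pd.DataFrame:
    cases = pd.read_csv(path)
    missing = [c for c in CASE_COLUMNS if c not in cases.columns]
    if missing:
        raise DataError(f"cases file missing columns: {missing}")
    for col in _DATETIME_CASE_COLS:
        cases[col] = pd.to_datetime(cases[col])
    return cases


def write_observations(obs: pd.DataFrame, path) -> None:
    cols = obs[OBS_COLUMNS]
    with open(path, "w") as fh:
        charted = pd.DatetimeIndex(cols["charted_time"]).strftime("%Y-%m-%dT%H:%M:%S")
        ingest = cols["ingest_time"]
        has_ingest = ingest.notna().to_numpy()
        ingest_str = np.where(
            has_ingest,
            pd.DatetimeIndex(ingest).strftime("%Y-%m-%dT%H:%M:%S"),
            "",
        )
        values = cols["value"].to_numpy()
        actions = cols["action"].to_numpy(dtype=object)
        for i, (cid, stream, name) in enumerate(
            zip(cols["case_id"], cols["stream"], cols["name"])
        ):
            rec = {
                "case_id": cid,
                "stream": stream,
                "name": name,
                "action": actions[i] if isinstance(actions[i], str) else None,
                "value": None if np.isnan(values[i]) else float(values[i]),
                "charted_time": charted[i],
                "ingest_time": ingest_str[i] if has_ingest[i] else None,
            }
            fh.write(json.dumps(rec, separators=(",", ":")))
            fh.write("\n")


def read_observations(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    if not records:
        return pd.DataFrame(columns=OBS_COLUMNS)
    obs = pd.DataFrame.from_records(records)
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise DataError(f"observations file missing keys: {missing}")
    obs["charted_time"] = pd.to_datetime(obs["charted_time"])
    obs["ingest_time"] = pd.to_datetime(obs["ingest_time"])
    obs["value"] = obs["value"].astype(float)
    return obs[OBS_COLUMNS]


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out["pred_time"] = pd.DatetimeIndex(out["pred_time"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def read_scores(path) -> pd.DataFrame:
    scores = pd.read_csv(path)
    scores["pred_time"] = pd.to_datetime(scores["pred_time"])
    return scores
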