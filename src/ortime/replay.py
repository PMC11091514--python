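"""Latency-respecting replay of the intraoperative feed, and tokenization.

The unit of prediction is the :class:`Snapshot`: everything the pipeline
would have had in hand about one case at elapsed minute ``t``.  Visibility
is governed by *ingestion* time, not charting time — an observation charted
at minute 8 with a 3-minute feed latency is absent from the minute-10 view
and present from minute 11 — which is what prevents information leaks when
backtesting a real-time model offline.

Tokenization maps free-form names (events, medications, actions, the
categorical preoperative fields, whitespace-split procedure-name words) to
dense integer ids through a frequency-built, frozen :class:`Vocabulary`
(0 = padding, 1 = unknown).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import OperatingWindow

PAD = 0
UNK = 1

VOCAB_FIELDS = (
    "event", "medication", "action", "service",
    "hospital", "location", "urgency", "procedure",
)


@dataclass
class Vocabulary:
    """Per-field token maps with reserved padding (0) and unknown (1) ids."""

    maps: dict = field(default_factory=dict)
    min_count: int = 1
    frozen: bool = True

    def id(self, fieldname: str, name: str) -> int:
        return self.maps[fieldname].get(name, UNK)

    def size(self, fieldname: str) -> int:
        return len(self.maps[fieldname]) + 2

    def names(self, fieldname: str) -> list:
        """Known names in id order (excludes padding/unknown)."""
        m = self.maps[fieldname]
        return sorted(m, key=m.get)

    def procedure_ids(self, text: str) -> list:
        return [self.id("procedure", w) for w in str(text).lower().split()]

    def digest(self) -> str:
        import hashlib

        payload = json.dumps(self.maps, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {"min_count": self.min_count, "maps": self.maps}, indent=0, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(maps=d["maps"], min_count=d.get("min_count", 1))


def build_vocab(cases: pd.DataFrame, observations: pd.DataFrame,
                min_count: int = 1) -> Vocabulary:
    """Build the token maps from training-window data only.

    Names with frequency below ``min_count`` are dropped and tokenize to the
    unknown id.  Ids are assigned by descending frequency, ties broken
    lexicographically, starting at 2 — deterministic for a given corpus.
    """
    if len(cases) == 0:
        raise DataError("cannot build a vocabulary from an empty training set")
    counters = {f: Counter() for f in VOCAB_FIELDS}
    ev = observations[observations["stream"] == "event"]
    counters["event"].update(ev["name"])
    med = observations[observations["stream"] == "medication"]
    counters["medication"].update(med["name"])
    counters["action"].update(med["action"].dropna())
    for f in ("service", "hospital", "location", "urgency"):
        counters[f].update(cases[f])
    for text in cases["procedure_name"]:
        counters["procedure"].update(str(text).lower().split())

    maps = {}
    for f, counter in counters.items():
        kept = sorted(
            (name for name, c in counter.items() if c >= min_count),
            key=lambda name: (-counter[name], name),
        )
        maps[f] = {name: i + 2 for i, name in enumerate(kept)}
    return Vocabulary(maps=maps, min_count=min_count)


# ===================================================================== #
# snapshots
# ===================================================================== #

@dataclass
class Snapshot:
    """The latency-respecting view of one case at elapsed minute ``t``.

    Offsets are minutes since anaesthesia start (charted time), so every
    offset lies in ``[0, t]``.  ``flowsheet`` maps each charted channel to
    ``(values, offsets)`` arrays over the visible lookback window;
    ``flowsheet_carry`` holds the last visible value older than the lookback.
    ``label`` is the actual total duration — scoring information, never a
    model input.
    """

    case_id: str
    t: int
    preop: dict
    event_tokens: list  # (token_id, offset_minutes)
    med_tokens: list  # (token_id, action_id, offset_minutes)
    flowsheet: dict  # channel -> (np.ndarray values, np.ndarray offsets)
    flowsheet_carry: dict  # channel -> last value before lookback, or None
    label: float
    pred_time: pd.Timestamp

    def __eq__(self, other) -> bool:
        if not isinstance(other, Snapshot):
            return NotImplemented
        if (self.case_id, self.t, self.preop, self.event_tokens,
                self.med_tokens, self.flowsheet_carry) != \
           (other.case_id, other.t, other.preop, other.event_tokens,
                other.med_tokens, other.flowsheet_carry):
            return False
        if abs(self.label - other.label) > 1e-9:
            return False
        if pd.Timestamp(self.pred_time) != pd.Timestamp(other.pred_time):
            return False
        if set(self.flowsheet) != set(other.flowsheet):
            return False
        return all(
            np.array_equal(self.flowsheet[ch][0], other.flowsheet[ch][0])
            and np.array_equal(self.flowsheet[ch][1], other.flowsheet[ch][1])
            for ch in self.flowsheet
        )


class _CaseReplayer:
    """Precomputed per-case arrays; builds the view at any minute t."""

    def __init__(self, case, obs: pd.DataFrame, vocab: Vocabulary,
                 lookback: float = 120.0):
        self.case = case
        self.vocab = vocab
        self.lookback = float(lookback)
        self.start = pd.Timestamp(case["anaesthesia_start"])
        self.T = int(np.floor(case["actual_duration"]))
        self.label = float(case["actual_duration"])
        self.case_id = case["case_id"]
        self.preop = {
            "hospital": case["hospital"],
            "service": case["service"],
            "location": case["location"],
            "urgency": case["urgency"],
            "procedure_name": case["procedure_name"],
            "scheduled_duration": float(case["scheduled_duration"]),
            "hospital_id": vocab.id("hospital", case["hospital"]),
            "service_id": vocab.id("service", case["service"]),
            "location_id": vocab.id("location", case["location"]),
            "urgency_id": vocab.id("urgency", case["urgency"]),
            "procedure_token_ids": vocab.procedure_ids(case["procedure_name"]),
        }
        start64 = np.datetime64(self.start).astype("datetime64[s]")

        stream = obs["stream"].to_numpy()
        charted = (obs["charted_time"].to_numpy().astype("datetime64[s]")
                   - start64).astype(np.float64) / 60.0
        ingest = (obs["ingest_time"].to_numpy().astype("datetime64[s]")
                  - start64).astype(np.float64) / 60.0
        names = obs["name"].to_numpy(dtype=object)

        # events and medications, sorted by ingestion so the visible set at
        # any t is a prefix
        ev = stream == "event"
        order = np.argsort(ingest[ev], kind="stable")
        self._ev_ingest = ingest[ev][order]
        self._ev_tokens = [
            (vocab.id("event", n), off)
            for n, off in zip(names[ev][order], charted[ev][order])
        ]
        med = stream == "medication"
        order = np.argsort(ingest[med], kind="stable")
        actions = obs["action"].to_numpy(dtype=object)[med][order]
        self._med_ingest = ingest[med][order]
        self._med_tokens = [
            (vocab.id("medication", n),
             vocab.id("action", a) if isinstance(a, str) else PAD,
             off)
            for n, a, off in zip(names[med][order], actions, charted[med][order])
        ]

        flow = stream == "flowsheet"
        values = obs["value"].to_numpy()
        self._flow = {}
        for ch in sorted(set(names[flow])):
            m = flow & (names == ch)
            order = np.argsort(charted[m], kind="stable")
            self._flow[ch] = (
                values[m][order], charted[m][order], ingest[m][order]
            )
        # pred_time per minute, computed once
        self._pred_times = start64 + (np.arange(self.T + 1) * 60).astype("timedelta64[s]")

    def snapshot(self, t: int) -> Snapshot:
        if not 1 <= t <= self.T:
            raise DataError(
                f"t={t} out of range [1, {self.T}] for case {self.case_id}"
            )
        k = int(np.searchsorted(self._ev_ingest, t, side="right"))
        event_tokens = self._ev_tokens[:k]
        k = int(np.searchsorted(self._med_ingest, t, side="right"))
        med_tokens = self._med_tokens[:k]
        flowsheet, carry = {}, {}
        horizon = t - self.lookback
        for ch, (vals, charted, ingest) in self._flow.items():
            vis = ingest <= t
            if horizon > 0:
                recent = vis & (charted > horizon)
                older = vis & (charted <= horizon)
                older_vals = vals[older]
                carry[ch] = float(older_vals[-1]) if len(older_vals) else None
                v = vals[recent]
                if len(v) or carry[ch] is not None:
                    flowsheet[ch] = (v, charted[recent])
            else:
                v = vals[vis]
                if len(v):
                    flowsheet[ch] = (v, charted[vis])
        return Snapshot(
            case_id=self.case_id,
            t=int(t),
            preop=self.preop,
            event_tokens=event_tokens,
            med_tokens=med_tokens,
            flowsheet=flowsheet,
            flowsheet_carry=carry,
            label=self.label,
            pred_time=self._pred_times[t],
        )


def replay(case: pd.Series, observations: pd.DataFrame, t: int,
           vocab: Vocabulary, lookback: float = 120.0) -> Snapshot:
    """The minute-``t`` view of one case.

    ``observations`` may contain other cases' rows; only rows matching
    ``case['case_id']`` are considered.  Raises :class:`DataError` if ``t``
    is outside ``[1, floor(actual_duration)]``.
    """
    obs = observations[observations["case_id"] == case["case_id"]]
    return _CaseReplayer(case, obs, vocab, lookback).snapshot(t)


def snapshot_stream(cases: pd.DataFrame, observations: pd.DataFrame,
                    vocab: Vocabulary, window: Optional[OperatingWindow] = None,
                    lookback: float = 120.0) -> Iterator[Snapshot]:
    """Yield one snapshot per case per live minute, chronological within case.

    For a fully in-window case of duration ``D`` this yields exactly
    ``floor(D)`` snapshots (minutes ``1..floor(D)``); with an operating
    window, only minutes at which the pipeline is live are yielded.
    """
    by_case = dict(iter(observations.groupby("case_id", sort=False)))
    empty = observations.iloc[0:0]
    for _, case in cases.iterrows():
        obs = by_case.get(case["case_id"], empty)
        rep = _CaseReplayer(case, obs, vocab, lookback)
        if rep.T < 1:
            continue
        ts = np.arange(1, rep.T + 1)
        if window is not None:
            times = rep.start + pd.to_timedelta(ts, unit="m")
            ts = ts[window.in_window(times)]
        for t in ts:
            yield rep.snapshot(int(t))


# ===================================================================== #
# persistence
# ===================================================================== #

def _snapshot_to_record(s: Snapshot) -> dict:
    return {
        "case_id": s.case_id,
        "t": s.t,
        "pred_time": pd.Timestamp(s.pred_time).isoformat(),
        "label": s.label,
        "preop": s.preop,
        "event_tokens": [[tok, off] for tok, off in s.event_tokens],
        "med_tokens": [[tok, act, off] for tok, act, off in s.med_tokens],
        "flowsheet": {
            ch: {"values": v.tolist(), "offsets": o.tolist()}
            for ch, (v, o) in s.flowsheet.items()
        },
        "flowsheet_carry": s.flowsheet_carry,
    }


def _snapshot_from_record(d: dict) -> Snapshot:
    return Snapshot(
        case_id=d["case_id"],
        t=int(d["t"]),
        preop=d["preop"],
        event_tokens=[(tok, off) for tok, off in d["event_tokens"]],
        med_tokens=[(tok, act, off) for tok, act, off in d["med_tokens"]],
        flowsheet={
            ch: (np.asarray(v["values"], dtype=float),
                 np.asarray(v["offsets"], dtype=float))
            for ch, v in d["flowsheet"].items()
        },
        flowsheet_carry=d["flowsheet_carry"],
        label=float(d["label"]),
        pred_time=pd.Timestamp(d["pred_time"]),
    )


def persist_snapshots(snapshots: Iterable[Snapshot], path) -> int:
    """Write snapshots as JSON lines; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for s in snapshots:
            fh.write(json.dumps(_snapshot_to_record(s), separators=(",", ":")))
            fh.write("\n")
            n += 1
    return n


def load_snapshots(path) -> Iterator[Snapshot]:
    """Stream snapshots back from a JSONL file written by persist_snapshots."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield _snapshot_from_record(json.loads(line))
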