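"""Snapshot featurization for the duration network.

The network consumes a fixed-length vector per snapshot.  Sequential inputs
(event/medication token streams, per-minute flowsheet channels) are
summarized into recency, count, level and trend features rather than fed as
raw sequences; the summaries are chosen so the signals that carry remaining-
duration information survive: the time since the most recent end-of-case
signature token (neuromuscular reversal, antiemetic, emergence), and the
expired-agent washout ratio.  Missing flowsheet channels are encoded with an
explicit presence mask, never imputed.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import FLOWSHEET_CHANNELS
from .errors import DataError
from .replay import Snapshot, Vocabulary
from .simulate import (
    ANTIEMETIC_MEDICATIONS,
    EMERGENCE_EVENTS,
    REVERSAL_MEDICATIONS,
    START_EVENTS,
)

# Channels whose absolute scale is ~100; scaled down so raw features are O(1).
_SCALE = {
    "heart_rate": 100.0,
    "bispectral_index": 100.0,
    "expired_nitrous_oxide": 100.0,
    "inspired_oxygen_fraction": 1.0,
    "expired_sevoflurane": 1.0,
    "expired_desflurane": 1.0,
}
_AGENT_CHANNELS = ("expired_sevoflurane", "expired_desflurane", "expired_nitrous_oxide")


class SnapshotVectorizer(TransformerMixin, BaseEstimator):
    """Turn snapshots into a dense feature matrix.

    Parameters
    ----------
    vocab
        The frozen vocabulary the snapshots were tokenized with; supplies
        the categorical one-hot layouts and the signature token ids.
    reversal_medications, antiemetic_medications, emergence_events, start_events
        Names whose recency is tracked explicitly.  Defaults match the
        synthetic generator's token names.
    since_cap
        Cap, in minutes, on "minutes since token" features.
    flow_since_cap
        Cap, in minutes, on "minutes since last flowsheet value" features.
    trend_window
        Minutes of flowsheet history used for level/trend summaries.
    """

    def __init__(self, vocab: Optional[Vocabulary] = None,
                 reversal_medications: tuple = REVERSAL_MEDICATIONS,
                 antiemetic_medications: tuple = ANTIEMETIC_MEDICATIONS,
                 emergence_events: tuple = EMERGENCE_EVENTS,
                 start_events: tuple = START_EVENTS,
                 since_cap: float = 60.0,
                 flow_since_cap: float = 30.0,
                 trend_window: int = 10):
        self.vocab = vocab
        self.reversal_medications = reversal_medications
        self.antiemetic_medications = antiemetic_medications
        self.emergence_events = emergence_events
        self.start_events = start_events
        self.since_cap = since_cap
        self.flow_since_cap = flow_since_cap
        self.trend_window = trend_window

    # ------------------------------------------------------------------ #

    def fit(self, X: Optional[Iterable[Snapshot]] = None, y=None):
        if self.vocab is None:
            raise DataError("SnapshotVectorizer requires a vocabulary")
        v = self.vocab
        self.hospital_names_ = v.names("hospital")
        self.service_names_ = v.names("service")
        self._rev_ids = {v.id("medication", n) for n in self.reversal_medications}
        self._anti_ids = {v.id("medication", n) for n in self.antiemetic_medications}
        self._emerg_ids = {v.id("event", n) for n in self.emergence_events}
        self._start_ids = {v.id("event", n) for n in self.start_events}
        names = [
            "scheduled_duration", "log_scheduled", "urgency_elective",
            "t", "log_t", "sched_minus_t", "sched_minus_t_pos",
            "frac_elapsed_of_sched", "past_schedule",
        ]
        names += [f"hospital={h}" for h in self.hospital_names_] + ["hospital=other"]
        names += [f"service={s}" for s in self.service_names_] + ["service=other"]
        names += [
            "n_event_tokens", "n_med_tokens",
            "start_event_seen", "start_event_since",
            "emergence_seen", "emergence_since",
            "reversal_seen", "reversal_since",
            "antiemetic_seen", "antiemetic_since",
            "endcase_seen", "endcase_since",
            "last_med_since",
        ]
        for ch in FLOWSHEET_CHANNELS:
            names += [
                f"{ch}:present", f"{ch}:last", f"{ch}:since",
                f"{ch}:recent_mean", f"{ch}:recent_trend",
            ]
            if ch in _AGENT_CHANNELS:
                names += [f"{ch}:washout_ratio"]
        self.feature_names_ = names
        self.n_features_in_ = len(names)
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    # ------------------------------------------------------------------ #

    def transform(self, X: Iterable[Snapshot]) -> np.ndarray:
        rows = [self._featurize(s) for s in X]
        if not rows:
            return np.empty((0, self.n_features_in_))
        return np.asarray(rows, dtype=np.float64)

    @staticmethod
    def _since(t: float, offsets: list, cap: float) -> tuple:
        """(seen, normalized minutes-since-most-recent) for a token offset list."""
        if not offsets:
            return 0.0, 1.0
        return 1.0, min(t - max(offsets), cap) / cap

    def _featurize(self, s: Snapshot) -> list:
        t = float(s.t)
        sched = float(s.preop["scheduled_duration"])
        row = [
            sched / 100.0,
            math.log1p(sched),
            1.0 if s.preop["urgency"] == "elective" else 0.0,
            t / 100.0,
            math.log1p(t),
            (sched - t) / 100.0,
            max(sched - t, 0.0) / 100.0,
            t / max(sched, 1.0),
            1.0 if t > sched else 0.0,
        ]
        hosp = s.preop["hospital"]
        row += [1.0 if hosp == h else 0.0 for h in self.hospital_names_]
        row += [1.0 if hosp not in self.hospital_names_ else 0.0]
        svc = s.preop["service"]
        row += [1.0 if svc == x else 0.0 for x in self.service_names_]
        row += [1.0 if svc not in self.service_names_ else 0.0]

        start_ids, emerg_ids = self._start_ids, self._emerg_ids
        rev_ids, anti_ids = self._rev_ids, self._anti_ids
        start_off = [off for tok, off in s.event_tokens if tok in start_ids]
        emerg_off = [off for tok, off in s.event_tokens if tok in emerg_ids]
        rev_off = [off for tok, _, off in s.med_tokens if tok in rev_ids]
        anti_off = [off for tok, _, off in s.med_tokens if tok in anti_ids]
        med_off = [off for _, _, off in s.med_tokens]
        end_off = emerg_off + rev_off + anti_off

        row += [len(s.event_tokens) / 10.0, len(s.med_tokens) / 10.0]
        cap = self.since_cap
        for offs in (start_off, emerg_off, rev_off, anti_off, end_off):
            row += self._since(t, offs, cap)
        row.append(self._since(t, med_off, cap)[1])

        w = float(self.trend_window)
        carry_map = s.flowsheet_carry or {}
        for ch in FLOWSHEET_CHANNELS:
            series = s.flowsheet.get(ch)
            scale = _SCALE[ch]
            if series is None or len(series[0]) == 0:
                carry = carry_map.get(ch)
                if carry is not None:
                    row += (1.0, carry / scale, 1.0, carry / scale, 0.0)
                else:
                    row += (0.0, 0.0, 1.0, 0.0, 0.0)
                if ch in _AGENT_CHANNELS:
                    row.append(0.0)
                continue
            vals, offs = series
            last = vals[-1] / scale
            since = min(t - offs[-1], self.flow_since_cap) / self.flow_since_cap
            # offsets are sorted; the recent window is a tail slice
            i = int(np.searchsorted(offs, offs[-1] - w, side="right"))
            recent = vals[i:]
            mean = float(recent.mean()) / scale
            trend = last - recent[0] / scale
            row += (1.0, float(last), float(since), mean, float(trend))
            if ch in _AGENT_CHANNELS:
                peak = float(vals.max()) / scale
                row.append(float(last / peak) if peak > 1e-9 else 0.0)
        return row


def featurize(snapshots: Iterable[Snapshot], vocab: Vocabulary,
              trend_window: int = 10):
    """Convenience: fit a default vectorizer and transform in one call.

    Returns ``(X, y_remaining, meta)`` where ``meta`` is a dict of aligned
    arrays (case_id, t, pred_time, label, scheduled_duration).
    """
    vec = SnapshotVectorizer(vocab=vocab, trend_window=trend_window).fit()
    rows, case_id, ts, pred_time, label, sched = [], [], [], [], [], []
    for s in snapshots:
        rows.append(vec._featurize(s))
        case_id.append(s.case_id)
        ts.append(s.t)
        pred_time.append(s.pred_time)
        label.append(s.label)
        sched.append(s.preop["scheduled_duration"])
    X = (np.asarray(rows, dtype=np.float64) if rows
         else np.empty((0, vec.n_features_in_)))
    y = np.asarray(label, dtype=float) - np.asarray(ts, dtype=float)
    meta = {
        "case_id": np.asarray(case_id, dtype=object),
        "t": np.asarray(ts, dtype=int),
        "pred_time": np.asarray(pred_time, dtype="datetime64[s]"),
        "label": np.asarray(label, dtype=float),
        "scheduled_duration": np.asarray(sched, dtype=float),
    }
    return X, y, meta
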