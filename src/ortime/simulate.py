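"""Synthetic operating-room data generator.

Produces a statistically structured stand-in for a real-time anaesthesia
record feed: a case table (scheduled vs actual durations linked by a known
linear map), per-minute flowsheet channels, intraoperative events and
medication administrations with end-of-case signatures (neuromuscular
reversal, antiemetic, emergence) placed a short, learnable interval before
anaesthesia stop, a charting-to-ingestion latency per stream type, and an
operating window (weekdays, daytime hours) with sporadic hour-block
downtime that censors which cases the pipeline captures.

Cases are returned as a :class:`pandas.DataFrame` (one row per anaesthetic)
and observations as a DataFrame with columns ``case_id, stream, name,
action, value, charted_time, ingest_time`` — the canonical on-disk layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import DataError

CASE_COLUMNS = [
    "case_id",
    "hospital",
    "location",
    "service",
    "urgency",
    "procedure_name",
    "scheduled_start",
    "scheduled_end",
    "scheduled_duration",
    "anaesthesia_start",
    "anaesthesia_stop",
    "actual_duration",
]

OBS_COLUMNS = [
    "case_id",
    "stream",
    "name",
    "action",
    "value",
    "charted_time",
    "ingest_time",
]

# Signature tokens the generator plants near anaesthesia stop; the feature
# extractor watches the same names by default.
REVERSAL_MEDICATIONS = ("sugammadex", "neostigmine")
ANTIEMETIC_MEDICATIONS = ("ondansetron",)
EMERGENCE_EVENTS = ("emergence",)
START_EVENTS = ("induction", "intubation")

_SIDES = ("left", "right", "bilateral", "")
_MODIFIERS = ("laparoscopic", "open", "robotic-assisted", "revision", "")
_VERBS = (
    "excision", "repair", "replacement", "biopsy", "resection",
    "bypass", "fusion", "exploration", "drainage", "reconstruction",
)
_ANATOMY = {
    "general surgery": ("inguinal hernia", "gallbladder", "colon", "appendix", "stomach"),
    "orthopaedics": ("knee", "hip", "shoulder", "femur", "ankle"),
    "otolaryngology": ("tonsil", "sinus", "thyroid", "larynx", "ear"),
    "urology": ("kidney", "bladder", "prostate", "ureter", "testis"),
    "gastroenterology": ("oesophagus", "duodenum", "colon polyp", "bile duct", "rectum"),
    "ophthalmology": ("cataract", "retina", "cornea", "eyelid", "lacrimal duct"),
    "neurosurgery": ("craniotomy site", "lumbar spine", "cervical spine", "pituitary", "shunt"),
    "cardiac surgery": ("aortic valve", "mitral valve", "coronary artery", "ascending aorta", "septum"),
    "plastic surgery": ("breast", "skin flap", "hand", "scar", "abdominal wall"),
    "vascular surgery": ("femoral artery", "carotid artery", "aorta", "fistula", "varicose vein"),
}
_GENERIC_ANATOMY = ("lesion", "mass", "wound", "abscess", "cyst")

_INTRAOP_EVENTS = (
    "incision", "positioning check", "tourniquet up", "tourniquet down",
    "specimen removed", "aortic clamp applied", "graft reperfusion",
    "dressing applied",
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Independent, reproducible substreams per generation stage.
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream]))


# ===================================================================== #
# cases
# ===================================================================== #

def generate_cases(config: SimConfig) -> pd.DataFrame:
    """Generate the case table.

    Deterministic given ``config.seed``.  Actual duration is drawn from a
    per-service log-normal; the scheduled duration is the rounded inverse
    of the configured linear link, and the realised actual duration is the
    link applied to the scheduled duration plus (optionally scheduled-
    duration-scaled) Gaussian noise, so ordinary least squares of actual on
    scheduled recovers the link.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    start = pd.Timestamp(config.start_date)
    days = start + pd.to_timedelta(np.arange(config.n_days), unit="D")
    weekday = days.weekday < 5
    rates = np.where(weekday, config.cases_per_weekday,
                     config.cases_per_weekday * config.weekend_factor)
    n_per_day = rng.poisson(rates)
    n = int(n_per_day.sum())
    if n == 0:
        raise DataError("configuration produced zero cases")
    day_idx = np.repeat(np.arange(config.n_days), n_per_day)
    case_day = days[day_idx]
    is_weekday = weekday[day_idx]

    hosp_names, hosp_p = config.hospital_probs()
    hospital = rng.choice(np.array(hosp_names, dtype=object), size=n, p=hosp_p)

    services, svc_p = config.service_probs()
    svc_idx = rng.choice(len(services), size=n, p=svc_p)
    service = np.array([s.name for s in services], dtype=object)[svc_idx]
    medians = np.array([s.median_minutes for s in services])[svc_idx]
    sigmas = np.array([s.sigma for s in services])[svc_idx]

    # Weekend lists are mostly urgent cases.
    p_elective = np.where(is_weekday, config.urgency_elective_prob,
                          config.urgency_elective_prob * 0.2)
    elective = rng.random(n) < p_elective
    urgency = np.where(elective, "elective", "non-elective").astype(object)

    # Skewed categorical over anaesthetising locations.
    loc_w = 1.0 / (np.arange(config.n_locations) + 1.0) ** 0.8
    loc_idx = rng.choice(config.n_locations, size=n, p=loc_w / loc_w.sum())
    location = np.array([f"OR-{i + 1:02d}" for i in range(config.n_locations)],
                        dtype=object)[loc_idx]

    procedure = _procedure_names(rng, service)

    link = config.schedule
    base = np.exp(np.log(medians) + sigmas * rng.standard_normal(n))
    scheduled = np.maximum(
        np.round((base - link.intercept) / link.slope), config.min_duration
    )
    noise_scale = link.noise_sd * (scheduled / link.ref_minutes) ** link.noise_exponent
    actual = link.slope * scheduled + link.intercept + noise_scale * rng.standard_normal(n)
    actual = np.maximum(actual, config.min_duration)

    # Elective lists start in the morning; urgent cases arrive around the clock.
    hour = np.where(
        elective,
        np.clip(rng.normal(9.5, 2.2, size=n), config.window_start, 17.0),
        rng.uniform(0.0, 24.0, size=n),
    )
    sched_start = (
        pd.DatetimeIndex(case_day)
        + pd.to_timedelta(np.round(hour * 60.0) * 60.0, unit="s")
    )
    jitter = np.clip(rng.normal(8.0, 12.0, size=n), -15.0, 60.0)
    anae_start = sched_start + pd.to_timedelta(np.round(jitter * 60.0), unit="s")
    anae_stop = anae_start + pd.to_timedelta(np.round(actual * 60.0), unit="s")
    actual = (anae_stop - anae_start).total_seconds() / 60.0  # exact to the second

    cases = pd.DataFrame(
        {
            "case_id": [f"C{i + 1:06d}" for i in range(n)],
            "hospital": hospital,
            "location": location,
            "service": service,
            "urgency": urgency,
            "procedure_name": procedure,
            "scheduled_start": sched_start,
            "scheduled_end": sched_start + pd.to_timedelta(scheduled, unit="m"),
            "scheduled_duration": scheduled,
            "anaesthesia_start": anae_start,
            "anaesthesia_stop": anae_stop,
            "actual_duration": actual,
        }
    )
    return cases.sort_values("anaesthesia_start", kind="stable").reset_index(drop=True)


def _procedure_names(rng: np.random.Generator, service: np.ndarray) -> np.ndarray:
    """High-cardinality free-text names from a small template grammar."""
    n = len(service)
    side = rng.choice(np.array(_SIDES, dtype=object), size=n)
    mod = rng.choice(np.array(_MODIFIERS, dtype=object), size=n)
    verb = rng.choice(np.array(_VERBS, dtype=object), size=n)
    out = np.empty(n, dtype=object)
    for i in range(n):
        pool = _ANATOMY.get(service[i], _GENERIC_ANATOMY)
        anatomy = pool[rng.integers(len(pool))]
        out[i] = " ".join(p for p in (mod[i], side[i], anatomy, verb[i]) if p)
    return out


# ===================================================================== #
# intraoperative streams
# ===================================================================== #

def generate_streams(cases: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate intraoperative observations (charted times only).

    Flowsheet values are charted once per whole elapsed minute ``1..floor(D)``.
    Start-of-case events land in the first minutes; the end-of-case
    signature tokens (reversal agent, antiemetic, emergence) are charted a
    uniform ``signature_offset`` (default 5–15 min) before anaesthesia stop,
    and the expired-agent channels wash out towards zero over the final
    ``washout_minutes`` — together these make remaining duration learnable
    from the stream.  ``ingest_time`` is left unset (NaT); see
    :func:`inject_latency`.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    frames = [
        _flowsheet_frame(cases, config, rng),
        _event_frame(cases, config, rng),
        _medication_frame(cases, config, rng),
    ]
    obs = pd.concat(frames, ignore_index=True)
    obs["ingest_time"] = pd.NaT
    obs = obs.sort_values(
        ["charted_time", "case_id", "stream", "name"], kind="stable"
    ).reset_index(drop=True)
    return obs[OBS_COLUMNS]


def _case_minutes(cases: pd.DataFrame):
    """Concatenated per-case whole-minute grids 1..floor(actual_duration)."""
    T = np.floor(cases["actual_duration"].to_numpy()).astype(int)
    idx = np.repeat(np.arange(len(cases)), T)
    within = np.arange(T.sum()) - np.repeat(np.concatenate([[0], np.cumsum(T)[:-1]]), T)
    minute = within + 1
    return T, idx, minute


def _segment_cumsum(x: np.ndarray, seg_lengths: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each segment boundary."""
    c = np.cumsum(x)
    starts = np.concatenate([[0], np.cumsum(seg_lengths)[:-1]])
    offset = np.repeat(c[starts] - x[starts], seg_lengths)
    return c - offset


def _flowsheet_frame(cases, config, rng) -> pd.DataFrame:
    n = len(cases)
    T, idx, minute = _case_minutes(cases)
    m = len(minute)
    start = cases["anaesthesia_start"].to_numpy()
    charted = start[idx] + (minute * 60).astype("timedelta64[s]")
    Trep = T[idx]
    wash = config.washout_minutes
    into_wash = np.maximum(minute - (Trep - wash), 0.0)

    rows_name, rows_val, rows_mask = [], [], []

    # heart rate: per-case baseline + bounded random walk, complete coverage
    hr_base = rng.normal(75.0, 9.0, size=n)
    steps = rng.normal(0.0, 1.2, size=m)
    hr = np.clip(hr_base[idx] + _segment_cumsum(steps, T), 45.0, 140.0)
    rows_name.append("heart_rate")
    rows_val.append(np.round(hr, 0))
    rows_mask.append(np.ones(m, dtype=bool))

    # inspired O2 fraction: high at induction and emergence, 0.5 maintenance
    fio2 = np.full(m, 0.5) + rng.normal(0.0, 0.015, size=m)
    fio2 = np.where((minute <= 5) | (minute > Trep - 3), 0.8, fio2)
    rows_name.append("inspired_oxygen_fraction")
    rows_val.append(np.round(np.clip(fio2, 0.21, 1.0), 2))
    rows_mask.append(np.ones(m, dtype=bool))

    # bispectral index: monitored in ~70% of cases, absent pre-induction,
    # rises during emergence
    bis_on = rng.random(n) < 0.7
    bis = rng.normal(42.0, 4.0, size=m)
    bis = np.where(into_wash > 0, bis + 4.5 * into_wash, bis)
    rows_name.append("bispectral_index")
    rows_val.append(np.round(np.clip(bis, 0, 98), 0))
    rows_mask.append(bis_on[idx] & (minute > 3))

    # volatile agents: one agent per case (or TIVA), onset ramp then washout
    agent_kind = rng.choice(3, size=n, p=[0.70, 0.25, 0.05])  # sevo/des/none
    steady = np.where(agent_kind == 0, rng.normal(2.0, 0.25, size=n),
                      rng.normal(5.5, 0.5, size=n))
    conc = steady[idx] * (1.0 - np.exp(-minute / 3.0)) * np.exp(-into_wash / 2.5)
    conc += rng.normal(0.0, 0.03, size=m)
    conc = np.round(np.clip(conc, 0.0, None), 2)
    rows_name.append("expired_sevoflurane")
    rows_val.append(conc)
    rows_mask.append((agent_kind == 0)[idx])
    rows_name.append("expired_desflurane")
    rows_val.append(conc)
    rows_mask.append((agent_kind == 1)[idx])

    # nitrous oxide in ~20% of cases
    n2o_on = rng.random(n) < 0.2
    n2o = 50.0 * (1.0 - np.exp(-minute / 3.0)) * np.exp(-into_wash / 2.5)
    n2o += rng.normal(0.0, 1.0, size=m)
    rows_name.append("expired_nitrous_oxide")
    rows_val.append(np.round(np.clip(n2o, 0.0, None), 1))
    rows_mask.append(n2o_on[idx])

    case_ids = cases["case_id"].to_numpy()
    parts = []
    for name, val, mask in zip(rows_name, rows_val, rows_mask):
        parts.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[idx[mask]],
                    "stream": "flowsheet",
                    "name": name,
                    "action": None,
                    "value": val[mask],
                    "charted_time": charted[mask],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _uniform_offset_rows(cases, rng, lo, hi, names, name_p=None):
    """One charted row per case at stop − U(lo, hi) minutes.

    For cases shorter than the offset (possible only for handcrafted case
    tables below ``min_duration``) the offset is clamped so the token still
    falls after anaesthesia start.
    """
    n = len(cases)
    u = rng.uniform(lo, hi, size=n)
    u = np.minimum(u, np.maximum(cases["actual_duration"].to_numpy() - 1.0, 0.5))
    stop = cases["anaesthesia_stop"].to_numpy()
    charted = stop - np.round(u * 60.0).astype("timedelta64[s]")
    if len(names) == 1:
        name = np.full(n, names[0], dtype=object)
    else:
        name = rng.choice(np.array(names, dtype=object), size=n, p=name_p)
    return cases["case_id"].to_numpy(), name, charted


def _event_frame(cases, config, rng) -> pd.DataFrame:
    n = len(cases)
    start = cases["anaesthesia_start"].to_numpy()
    T = np.floor(cases["actual_duration"].to_numpy())
    lo, hi = config.signature_offset
    ids, names, times = [], [], []

    # start-of-case events within the first minutes
    ind_min = rng.uniform(1.0, 3.0, size=n)
    ids.append(cases["case_id"].to_numpy())
    names.append(np.full(n, "induction", dtype=object))
    times.append(start + np.round(ind_min * 60).astype("timedelta64[s]"))

    tube = rng.random(n) < 0.85
    tube_min = ind_min + rng.uniform(1.0, 4.0, size=n)
    ids.append(cases["case_id"].to_numpy()[tube])
    names.append(np.full(int(tube.sum()), "intubation", dtype=object))
    times.append((start + np.round(tube_min * 60).astype("timedelta64[s]"))[tube])

    # sporadic intraoperative events
    k = rng.poisson(np.maximum(T, 10.0) / 60.0)
    rep = np.repeat(np.arange(n), k)
    ev_min = rng.uniform(5.0, np.maximum(np.repeat(T, k) - 5.0, 6.0))
    ids.append(cases["case_id"].to_numpy()[rep])
    names.append(rng.choice(np.array(_INTRAOP_EVENTS, dtype=object), size=len(rep)))
    times.append(start[rep] + np.round(ev_min * 60).astype("timedelta64[s]"))

    # emergence signature before stop
    cid, name, charted = _uniform_offset_rows(cases, rng, lo, hi, EMERGENCE_EVENTS)
    ids.append(cid)
    names.append(name)
    times.append(charted)

    return pd.DataFrame(
        {
            "case_id": np.concatenate(ids),
            "stream": "event",
            "name": np.concatenate(names),
            "action": None,
            "value": np.nan,
            "charted_time": np.concatenate(times),
        }
    )


def _medication_frame(cases, config, rng) -> pd.DataFrame:
    n = len(cases)
    start = cases["anaesthesia_start"].to_numpy()
    T = np.floor(cases["actual_duration"].to_numpy())
    lo, hi = config.signature_offset
    ids, names, actions, times = [], [], [], []

    def add(cid, name, action, charted):
        ids.append(cid)
        names.append(name)
        actions.append(action)
        times.append(charted)

    # induction agents
    ind_min = rng.uniform(0.5, 3.0, size=n)
    add(cases["case_id"].to_numpy(), np.full(n, "propofol", dtype=object),
        np.full(n, "given", dtype=object),
        start + np.round(ind_min * 60).astype("timedelta64[s]"))
    roc = rng.random(n) < 0.8
    add(cases["case_id"].to_numpy()[roc],
        np.full(int(roc.sum()), "rocuronium", dtype=object),
        np.full(int(roc.sum()), "given", dtype=object),
        (start + np.round((ind_min + rng.uniform(0.2, 1.5, size=n)) * 60)
         .astype("timedelta64[s]"))[roc])

    # intraoperative boluses / infusion adjustments
    for med, rate, act_pool in (
        ("fentanyl", 45.0, ("given",)),
        ("phenylephrine", 90.0, ("given", "rate adjustment")),
    ):
        k = rng.poisson(np.maximum(T, 10.0) / rate)
        rep = np.repeat(np.arange(n), k)
        mmin = rng.uniform(2.0, np.maximum(np.repeat(T, k) - 2.0, 3.0))
        act = rng.choice(np.array(act_pool, dtype=object), size=len(rep))
        add(cases["case_id"].to_numpy()[rep], np.full(len(rep), med, dtype=object),
            act, start[rep] + np.round(mmin * 60).astype("timedelta64[s]"))

    # end-of-case signatures: every case gets a reversal agent and an antiemetic
    cid, name, charted = _uniform_offset_rows(
        cases, rng, lo, hi, REVERSAL_MEDICATIONS, name_p=[0.6, 0.4]
    )
    add(cid, name, np.full(n, "given", dtype=object), charted)
    cid, name, charted = _uniform_offset_rows(cases, rng, lo, hi, ANTIEMETIC_MEDICATIONS)
    add(cid, name, np.full(n, "given", dtype=object), charted)

    return pd.DataFrame(
        {
            "case_id": np.concatenate(ids),
            "stream": "medication",
            "name": np.concatenate(names),
            "action": np.concatenate(actions),
            "value": np.nan,
            "charted_time": np.concatenate(times),
        }
    )


# ===================================================================== #
# latency
# ===================================================================== #

def inject_latency(observations: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Set ``ingest_time = charted_time + max(0, N(mean, sd))`` per stream type.

    Defaults are the observed production latencies (3.22/3.26/2.72 min for
    medications/events/flowsheet).  Negative draws are truncated to zero:
    data cannot be ingested before it is charted.
    """
    config.validate()
    if observations["ingest_time"].notna().any():
        raise DataError("observations already carry ingest_time")
    rng = _rng(config.seed, 2)
    obs = observations.copy()
    delay = np.zeros(len(obs))
    stream = obs["stream"].to_numpy()
    # Fixed stream order keeps draws reproducible regardless of row order
    # within a stream type.
    for s in ("event", "medication", "flowsheet"):
        mask = stream == s
        spec = config.latency[s]
        delay[mask] = np.maximum(
            rng.normal(spec.mean, spec.sd, size=int(mask.sum())), 0.0
        )
    obs["ingest_time"] = obs["charted_time"] + pd.to_timedelta(
        np.round(delay * 60.0), unit="s"
    )
    return obs


# ===================================================================== #
# operating window
# ===================================================================== #

@dataclass
class OperatingWindow:
    """Weekday daytime window plus a set of downtime hour blocks."""

    window_start: int = 7
    window_end: int = 19
    down_hours: np.ndarray = field(default_factory=lambda: np.array([], dtype="datetime64[h]"))

    def in_window(self, times) -> np.ndarray:
        """Boolean mask: pipeline live at each timestamp."""
        t = pd.DatetimeIndex(times)
        ok = (t.weekday < 5) & (t.hour >= self.window_start) & (t.hour < self.window_end)
        if len(self.down_hours):
            blocks = t.floor("h").values.astype("datetime64[h]")
            ok &= ~np.isin(blocks, self.down_hours)
        return np.asarray(ok)


def build_operating_window(config: SimConfig) -> OperatingWindow:
    """Sample the downtime blocks over the configured span, deterministic in
    the seed.  The span is derived from the config (not from data), so the
    same window is reconstructed no matter which subset of cases is in hand.
    """
    rng = _rng(config.seed, 3)
    start = pd.Timestamp(config.start_date).normalize()
    # a couple of days of slack for cases running past the last start day
    days = pd.date_range(start, start + pd.Timedelta(days=config.n_days + 2),
                         freq="D")
    days = days[days.weekday < 5]
    hours = np.arange(config.window_start, config.window_end)
    blocks = (days.values[:, None].astype("datetime64[h]")
              + hours[None, :].astype("timedelta64[h]")).ravel()
    down = blocks[rng.random(len(blocks)) < config.downtime_prob]
    return OperatingWindow(config.window_start, config.window_end, down)


def apply_operating_window(observations: pd.DataFrame, cases: pd.DataFrame,
                           config: SimConfig):
    """Censor the feed to what the pipeline captures.

    A case is captured when the pipeline registers it, i.e. when the feed is
    live (weekday, in-hours, not a downtime block) at anaesthesia start; a
    case whose entire course falls outside the window is therefore never
    captured.  Returns ``(kept_cases, kept_observations, capture_log)``; the
    log carries the counts, the capture fraction and the
    :class:`OperatingWindow` (whose downtime blocks `snapshot_stream` must
    reuse).
    """
    config.validate()
    window = build_operating_window(config)
    T, idx, minute = _case_minutes(cases)
    times = (cases["anaesthesia_start"].to_numpy()[idx]
             + (minute * 60).astype("timedelta64[s]"))
    live = window.in_window(times)
    n_live = np.zeros(len(cases), dtype=int)
    np.add.at(n_live, idx, live.astype(int))
    captured = np.asarray(window.in_window(cases["anaesthesia_start"])) & (n_live > 0)

    kept_cases = cases.loc[captured].reset_index(drop=True)
    kept_obs = observations[
        observations["case_id"].isin(set(kept_cases["case_id"]))
    ].reset_index(drop=True)
    log = {
        "n_cases": int(len(cases)),
        "n_captured": int(captured.sum()),
        "capture_fraction": float(captured.mean()),
        "n_down_hours": int(len(window.down_hours)),
        "in_window_minutes": {
            cid: int(k) for cid, k in zip(cases["case_id"], n_live) if k > 0
        },
        "window": window,
    }
    return kept_cases, kept_obs, log


def simulate(config: SimConfig):
    """Run the full generator: cases -> streams -> latency -> window."""
    cases = generate_cases(config)
    obs = generate_streams(cases, config)
    obs = inject_latency(obs, config)
    return apply_operating_window(obs, cases, config)
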