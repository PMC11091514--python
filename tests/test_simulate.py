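"""Statistical and structural checks of the synthetic operating-room feed."""

import numpy as np
import pandas as pd
import pytest

from ortime import ConfigError, ScheduleLink, SimConfig
from ortime.config import LatencySpec
from ortime.simulate import (
    OperatingWindow,
    apply_operating_window,
    generate_cases,
    generate_streams,
    inject_latency,
    REVERSAL_MEDICATIONS,
)

from conftest import make_case


def _small_cfg(**kw):
    base = dict(n_days=10, cases_per_weekday=20, seed=5)
    base.update(kw)
    return SimConfig(**base)


# ------------------------------------------------------------------ config

@pytest.mark.parametrize(
    "field, value",
    [
        ("n_days", 0),
        ("urgency_elective_prob", 1.5),
        ("downtime_prob", -0.1),
        ("n_locations", 0),
        ("min_duration", 0.0),
    ],
)
def test_invalid_config_raises_naming_field(field, value):
    cfg = _small_cfg(**{field: value})
    with pytest.raises(ConfigError, match=field.split("_")[0]):
        cfg.validate()


def test_invalid_nested_config():
    with pytest.raises(ConfigError, match="slope"):
        _small_cfg(schedule=ScheduleLink(slope=0.0)).validate()
    with pytest.raises(ConfigError, match="latency"):
        SimConfig(latency={"event": LatencySpec(3, 1)}).validate()
    with pytest.raises(ConfigError, match="window"):
        _small_cfg(window_start=19, window_end=7).validate()


# ------------------------------------------------------------------ cases

def test_noiseless_identity_link():
    """With slope 1, intercept 0, sd 0 the scheduled and actual durations
    coincide exactly for every case."""
    cfg = _small_cfg(schedule=ScheduleLink(slope=1.0, intercept=0.0, noise_sd=0.0))
    cases = generate_cases(cfg)
    assert np.allclose(cases["scheduled_duration"], cases["actual_duration"])


def test_case_table_invariants():
    cases = generate_cases(_small_cfg())
    assert (cases["actual_duration"] > 0).all()
    assert (cases["scheduled_duration"] > 0).all()
    dur = (cases["anaesthesia_stop"] - cases["anaesthesia_start"]).dt.total_seconds() / 60
    assert np.allclose(dur, cases["actual_duration"])
    sched = (cases["scheduled_end"] - cases["scheduled_start"]).dt.total_seconds() / 60
    assert np.allclose(sched, cases["scheduled_duration"])
    assert cases["case_id"].is_unique


def test_generate_cases_deterministic():
    a = generate_cases(_small_cfg())
    b = generate_cases(_small_cfg())
    pd.testing.assert_frame_equal(a, b)
    c = generate_cases(_small_cfg(seed=6))
    assert not a["actual_duration"].equals(c["actual_duration"])


def test_per_service_medians_match_configured():
    """Empirical per-service medians track the configured log-normal medians
    within 10% at n~2000."""
    cfg = SimConfig(n_days=60, cases_per_weekday=47, seed=2)
    cases = generate_cases(cfg)
    assert len(cases) > 1800
    configured = {s.name: s.median_minutes for s in cfg.services}
    # the linear link maps the log-normal base onto the realised duration
    for service, grp in cases.groupby("service"):
        if len(grp) < 150:
            continue
        med = grp["actual_duration"].median()
        assert med == pytest.approx(configured[service], rel=0.10)


def test_population_duration_realistic():
    """Median ~76-83 min and mean ~112-124 min, asserted loosely (+-20%)."""
    cases = generate_cases(SimConfig(n_days=90, seed=1))
    assert 76 * 0.8 <= cases["actual_duration"].median() <= 83 * 1.2
    assert 112 * 0.8 <= cases["actual_duration"].mean() <= 124 * 1.2


def test_hospital_volumes_follow_weights():
    cfg = SimConfig(n_days=60, cases_per_weekday=40, seed=3)
    cases = generate_cases(cfg)
    names, probs = cfg.hospital_probs()
    freq = cases["hospital"].value_counts(normalize=True)
    for name, p in zip(names, probs):
        assert freq[name] == pytest.approx(p, abs=0.03)


# ------------------------------------------------------------------ streams

def test_flowsheet_cadence_one_heart_rate_per_minute():
    """A 10-minute case yields exactly 10 heart-rate observations, at whole
    minutes 1..10."""
    case = make_case(duration=10.6)
    obs = generate_streams(case, _small_cfg())
    hr = obs[obs["name"] == "heart_rate"]
    assert len(hr) == 10
    mins = (hr["charted_time"] - case["anaesthesia_start"].iloc[0]).dt.total_seconds() / 60
    assert sorted(mins) == list(range(1, 11))


def test_reversal_agent_in_signature_window():
    """Every case carries a reversal-agent administration charted 5-15 min
    before anaesthesia stop."""
    cases = generate_cases(_small_cfg())
    obs = generate_streams(cases, _small_cfg())
    rev = obs[obs["name"].isin(REVERSAL_MEDICATIONS)]
    assert set(rev["case_id"]) == set(cases["case_id"])
    stop = cases.set_index("case_id")["anaesthesia_stop"]
    gap = (stop.loc[rev["case_id"]].to_numpy() - rev["charted_time"].to_numpy())
    gap_min = gap.astype("timedelta64[s]").astype(float) / 60.0
    assert (gap_min >= 5.0 - 1e-9).all() and (gap_min <= 15.0 + 1e-9).all()
    assert (rev["action"] == "given").all()


def test_mean_signature_offset_matches_configured():
    """Over ~500 cases the mean stop-minus-last-reversal gap sits near the
    centre of the configured U(5,15) offset."""
    cfg = SimConfig(n_days=15, cases_per_weekday=48, seed=9)
    cases = generate_cases(cfg)
    assert len(cases) >= 500
    obs = generate_streams(cases, cfg)
    rev = obs[obs["name"].isin(REVERSAL_MEDICATIONS)]
    last = rev.groupby("case_id")["charted_time"].max()
    stop = cases.set_index("case_id")["anaesthesia_stop"]
    gap = (stop - last).dt.total_seconds() / 60.0
    assert 5.0 <= gap.mean() <= 15.0
    assert gap.mean() == pytest.approx(10.0, abs=0.5)


def test_agent_washout_towards_zero():
    """Expired agent concentration in the final minutes decays well below
    its intra-case peak."""
    cases = generate_cases(_small_cfg()).head(40)
    obs = generate_streams(cases, _small_cfg())
    agents = obs[obs["name"].isin(["expired_sevoflurane", "expired_desflurane"])]
    for cid, grp in agents.groupby("case_id"):
        grp = grp.sort_values("charted_time")
        if len(grp) < 25:
            continue
        assert grp["value"].iloc[-1] < 0.5 * grp["value"].max()


def test_end_of_case_signal_tightens_remaining_duration(medium_sim):
    """Conditioning on the reversal token shrinks the spread of remaining
    duration far below its marginal spread — the signal that makes the
    model-beats-benchmark comparison meaningful."""
    cfg, cases, obs, _ = medium_sim
    assert len(cases) >= 500
    rev = obs[obs["name"].isin(REVERSAL_MEDICATIONS)]
    first = rev.groupby("case_id")["charted_time"].min()
    stop = cases.set_index("case_id")["anaesthesia_stop"]
    remaining_given_signal = (stop.loc[first.index] - first).dt.total_seconds() / 60.0
    rng = np.random.default_rng(0)
    T = np.floor(cases["actual_duration"].to_numpy())
    t = rng.integers(1, T + 1)
    marginal_remaining = cases["actual_duration"].to_numpy() - t
    assert remaining_given_signal.std() < 0.5 * marginal_remaining.std()


# ------------------------------------------------------------------ latency

def test_latency_constant_and_zero_limits():
    cases = generate_cases(_small_cfg()).head(5)
    streams = generate_streams(cases, _small_cfg())
    const = {s: LatencySpec(3.0, 0.0) for s in ("event", "medication", "flowsheet")}
    obs = inject_latency(streams, _small_cfg(latency=const))
    delay = (obs["ingest_time"] - obs["charted_time"]).dt.total_seconds() / 60
    assert np.allclose(delay, 3.0)
    zero = {s: LatencySpec(0.0, 0.0) for s in ("event", "medication", "flowsheet")}
    obs = inject_latency(streams, _small_cfg(latency=zero))
    assert (obs["ingest_time"] == obs["charted_time"]).all()


def test_latency_defaults_match_observed_means(medium_sim):
    """Empirical medication latency within 0.1 min of the 3.22-min default
    (>=10000 medication observations); no negative latency anywhere."""
    _, cases, obs, _ = medium_sim
    delay = (obs["ingest_time"] - obs["charted_time"]).dt.total_seconds() / 60.0
    assert (delay >= 0).all()
    med = delay[obs["stream"] == "medication"]
    assert len(med) >= 10_000
    assert med.mean() == pytest.approx(3.22, abs=0.1)
    ev = delay[obs["stream"] == "event"]
    assert ev.mean() == pytest.approx(3.26, abs=0.1)
    fl = delay[obs["stream"] == "flowsheet"]
    assert fl.mean() == pytest.approx(2.72, abs=0.1)


# ------------------------------------------------------------------ window

def test_window_captures_all_daytime_weekday_cases():
    """No downtime + every case on a weekday 08:00-17:00 -> 100% captured."""
    cfg = _small_cfg(downtime_prob=0.0)
    frames = [
        make_case(case_id=f"C{d}{h:02d}", start=f"2023-01-{d:02d} {h:02d}:00:00",
                  duration=45)
        for d in (2, 3, 4, 5, 6)  # Mon-Fri
        for h in (8, 11, 14, 17)
    ]
    cases = pd.concat(frames, ignore_index=True)
    obs = inject_latency(generate_streams(cases, cfg), cfg)
    kept, _, log = apply_operating_window(obs, cases, cfg)
    assert log["capture_fraction"] == 1.0
    assert len(kept) == len(cases)


def test_saturday_case_not_captured():
    cfg = _small_cfg(downtime_prob=0.0)
    sat = make_case(case_id="SAT", start="2023-01-07 10:00:00", duration=60)
    mon = make_case(case_id="MON", start="2023-01-09 10:00:00", duration=60)
    cases = pd.concat([sat, mon], ignore_index=True)
    obs = inject_latency(generate_streams(cases, cfg), cfg)
    kept, kept_obs, _ = apply_operating_window(obs, cases, cfg)
    assert list(kept["case_id"]) == ["MON"]
    assert set(kept_obs["case_id"]) == {"MON"}


def test_capture_fraction_near_study_value():
    """Defaults give ~74% capture over ~5000 cases."""
    cfg = SimConfig(n_days=105, cases_per_weekday=65, seed=5)
    cases = generate_cases(cfg)
    assert len(cases) >= 4500
    obs = inject_latency(generate_streams(cases, cfg), cfg)
    _, _, log = apply_operating_window(obs, cases, cfg)
    assert log["capture_fraction"] == pytest.approx(0.74, abs=0.05)


def test_operating_window_mask():
    w = OperatingWindow(7, 19, np.array(["2023-01-04T09"], dtype="datetime64[h]"))
    times = pd.to_datetime([
        "2023-01-04 08:30",  # weekday, in hours
        "2023-01-04 09:30",  # downtime block
        "2023-01-04 19:30",  # after hours
        "2023-01-07 10:00",  # Saturday
    ])
    assert w.in_window(times).tolist() == [True, False, False, False]


# ------------------------------------------------------------------ determinism

def test_identical_config_gives_byte_identical_files(tmp_path):
    from ortime import io as ortio
    from ortime.simulate import simulate

    for tag in ("a", "b"):
        cfg = SimConfig(n_days=6, cases_per_weekday=8, seed=42)
        cases, obs, _ = simulate(cfg)
        ortio.write_cases(cases, tmp_path / f"cases_{tag}.csv")
        ortio.write_observations(obs, tmp_path / f"obs_{tag}.jsonl")
    assert (tmp_path / "cases_a.csv").read_bytes() == (tmp_path / "cases_b.csv").read_bytes()
    assert (tmp_path / "obs_a.jsonl").read_bytes() == (tmp_path / "obs_b.jsonl").read_bytes()
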