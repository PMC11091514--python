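"""Configuration objects for the synthetic operating-room generator.

The generator emulates the data feed of a multi-hospital anaesthesia record
system: a population of surgical cases (with scheduled and actual durations),
per-minute intraoperative observation streams, a charting-to-ingestion
latency, and an operating window with sporadic downtime during which the
feed is live.  All knobs live on :class:`SimConfig`; every random draw is
governed by its single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .errors import ConfigError

#: The six per-minute charted physiological / machine channels.
FLOWSHEET_CHANNELS = (
    "expired_sevoflurane",
    "expired_desflurane",
    "expired_nitrous_oxide",
    "inspired_oxygen_fraction",
    "bispectral_index",
    "heart_rate",
)

STREAM_TYPES = ("event", "medication", "flowsheet")


@dataclass(frozen=True)
class ServiceSpec:
    """Duration model for one surgical service.

    Durations are log-normal: ``median_minutes`` is the median and ``sigma``
    the log-scale dispersion, so the mean is ``median * exp(sigma**2 / 2)``.
    """

    name: str
    weight: float
    median_minutes: float
    sigma: float


@dataclass(frozen=True)
class LatencySpec:
    """Charting-to-ingestion delay for one stream type, minutes."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ScheduleLink:
    """Linear link between scheduled and actual duration.

    Actual duration is generated as ``slope * scheduled + intercept + eps``
    with ``eps ~ N(0, (noise_sd * (scheduled / ref_minutes)**noise_exponent)**2)``,
    so an ordinary least-squares regression of actual on scheduled recovers
    (slope, intercept) without attenuation.  ``noise_exponent > 0`` makes
    longer cases noisier, which is what real theatre schedules look like.
    """

    slope: float = 0.99
    intercept: float = -4.4
    noise_sd: float = 30.0
    noise_exponent: float = 0.5
    ref_minutes: float = 100.0


def _default_hospitals() -> dict:
    # Case-volume shares of one academic adult, one academic paediatric and
    # two community hospitals (roughly 58/15/20/7).
    return {
        "academic_adult": 0.583,
        "academic_paeds": 0.154,
        "community_a": 0.201,
        "community_b": 0.062,
    }


def _default_services() -> tuple:
    # Mixture tuned so the population median duration lands near 80 min and
    # the mean near 115 min (right-skewed log-normals).
    return (
        ServiceSpec("general surgery", 0.17, 90.0, 0.62),
        ServiceSpec("orthopaedics", 0.13, 100.0, 0.57),
        ServiceSpec("otolaryngology", 0.10, 70.0, 0.57),
        ServiceSpec("urology", 0.10, 75.0, 0.62),
        ServiceSpec("gastroenterology", 0.14, 40.0, 0.50),
        ServiceSpec("ophthalmology", 0.11, 35.0, 0.45),
        ServiceSpec("neurosurgery", 0.07, 180.0, 0.57),
        ServiceSpec("cardiac surgery", 0.05, 250.0, 0.50),
        ServiceSpec("plastic surgery", 0.06, 95.0, 0.62),
        ServiceSpec("vascular surgery", 0.07, 130.0, 0.57),
    )


def _default_latency() -> dict:
    # Defaults are the observed production latencies of a minute-cadence
    # EHR-to-research-server feed.
    return {
        "event": LatencySpec(3.26, 1.17),
        "medication": LatencySpec(3.22, 1.13),
        "flowsheet": LatencySpec(2.72, 1.08),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic operating-room generator."""

    n_days: int = 60
    start_date: str = "2023-01-02"  # a Monday
    cases_per_weekday: float = 55.0
    weekend_factor: float = 0.18
    hospitals: Mapping[str, float] = field(default_factory=_default_hospitals)
    services: Sequence[ServiceSpec] = field(default_factory=_default_services)
    n_locations: int = 40
    urgency_elective_prob: float = 0.85
    schedule: ScheduleLink = field(default_factory=ScheduleLink)
    latency: Mapping[str, LatencySpec] = field(default_factory=_default_latency)
    window_start: int = 7  # hour of day, inclusive
    window_end: int = 19  # hour of day, exclusive
    downtime_prob: float = 0.10  # per weekday in-window hour block
    min_duration: float = 20.0  # minutes; shortest anaesthetic generated
    signature_offset: tuple = (5.0, 15.0)  # end-of-case tokens, min before stop
    washout_minutes: float = 8.0  # expired-agent decay tail
    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> "SimConfig":
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.cases_per_weekday <= 0:
            raise ConfigError("cases_per_weekday must be > 0")
        for name, p in (
            ("weekend_factor", self.weekend_factor),
            ("urgency_elective_prob", self.urgency_elective_prob),
            ("downtime_prob", self.downtime_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not self.hospitals or any(w < 0 for w in self.hospitals.values()):
            raise ConfigError("hospitals weights must be nonnegative and nonempty")
        if sum(self.hospitals.values()) <= 0:
            raise ConfigError("hospitals weights must sum to a positive value")
        if not self.services:
            raise ConfigError("services must be nonempty")
        for s in self.services:
            if s.weight < 0:
                raise ConfigError(f"services[{s.name}].weight must be >= 0")
            if s.median_minutes <= 0:
                raise ConfigError(f"services[{s.name}].median_minutes must be > 0")
            if s.sigma < 0:
                raise ConfigError(f"services[{s.name}].sigma must be >= 0")
        if sum(s.weight for s in self.services) <= 0:
            raise ConfigError("services weights must sum to a positive value")
        if self.n_locations < 1:
            raise ConfigError("n_locations must be >= 1")
        if self.schedule.slope <= 0:
            raise ConfigError("schedule.slope must be > 0")
        if self.schedule.noise_sd < 0:
            raise ConfigError("schedule.noise_sd must be >= 0")
        missing = [s for s in STREAM_TYPES if s not in self.latency]
        if missing:
            raise ConfigError(f"latency missing stream types: {missing}")
        for stream, spec in self.latency.items():
            if spec.sd < 0:
                raise ConfigError(f"latency[{stream}].sd must be >= 0")
        if not 0 <= self.window_start < self.window_end <= 24:
            raise ConfigError("window_start must be < window_end within [0, 24]")
        if self.min_duration <= 0:
            raise ConfigError("min_duration must be > 0")
        lo, hi = self.signature_offset
        if not 0 <= lo <= hi:
            raise ConfigError("signature_offset must satisfy 0 <= lo <= hi")
        if hi + lo > self.min_duration:
            raise ConfigError(
                "signature_offset upper bound incompatible with min_duration"
            )
        return self

    # ------------------------------------------------------------------ #

    def hospital_probs(self) -> "tuple[list, list]":
        total = sum(self.hospitals.values())
        names = list(self.hospitals)
        return names, [self.hospitals[n] / total for n in names]

    def service_probs(self) -> "tuple[list, list]":
        total = sum(s.weight for s in self.services)
        return list(self.services), [s.weight / total for s in self.services]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], Mapping):
            d["schedule"] = ScheduleLink(**d["schedule"])
        if "services" in d:
            d["services"] = tuple(
                s if isinstance(s, ServiceSpec) else ServiceSpec(**s)
                for s in d["services"]
            )
        if "latency" in d:
            d["latency"] = {
                k: v if isinstance(v, LatencySpec) else LatencySpec(**v)
                for k, v in d["latency"].items()
            }
        if "signature_offset" in d:
            d["signature_offset"] = tuple(d["signature_offset"])
        return cls(**d)


@dataclass
class ModelSpec:
    """Hyper-parameters of the probabilistic duration network.

    The network maps a fixed-length snapshot feature vector to a histogram
    over remaining duration: ``n_bins`` geometric bins spanning
    ``[0, max_minutes]``.  ``loss`` is ``"crps"`` (discretised continuous
    ranked probability score, the evaluation metric itself) or ``"xent"``
    (cross-entropy on the label's bin).
    """

    hidden: tuple = (96, 96)
    n_bins: int = 128
    max_minutes: float = 1440.0
    loss: str = "crps"
    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 512
    l2: float = 0.2
    seed: int = 0
    trend_window: int = 10  # minutes of flowsheet history for trend features

    def validate(self) -> "ModelSpec":
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.max_minutes <= 0:
            raise ConfigError("max_minutes must be > 0")
        if self.loss not in ("crps", "xent"):
            raise ConfigError("loss must be 'crps' or 'xent'")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if "hidden" in d:
            d["hidden"] = tuple(d["hidden"])
        return cls(**d)
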