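"""Performance-drift quantification and the retraining comparison.

Drift is measured on the weekly-batched ratio of mean model CRPS to mean
benchmark CRPS (batching by ISO week damps outliers; ratio < 1 means the
model is beating the bias-corrected schedule).  An ordinary least-squares
regression of the weekly ratio on week index gives the drift slope with a
95% t-interval; a slope indistinguishable from zero means performance is
holding relative to the benchmark.

The retraining comparison trains a second model with the identical spec on
a more recent (proximal) window, never exposed to the primary window's
data, and scores both on a later disjoint comparison window, reporting the
paired per-prediction CRPS difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ModelSpec
from .errors import ConfigError, DataError
from .models import fit_baseline, train_model
from .replay import build_vocab, snapshot_stream
from .scoring import score_predictions


@dataclass
class DriftResult:
    """Weekly ratio table plus the OLS drift slope (ratio units per week)."""

    weekly: pd.DataFrame
    slope: float
    slope_ci: tuple
    intercept: float
    n_weeks: int


def _iso_week_start(ts: pd.Series) -> pd.Series:
    """Monday 00:00 of each timestamp's ISO week."""
    t = pd.DatetimeIndex(ts).normalize()
    return t - pd.to_timedelta(t.weekday, unit="D")


def drift(scores: pd.DataFrame) -> DriftResult:
    """Weekly-batched CRPS-ratio regression over a score table."""
    if len(scores) == 0:
        raise DataError("empty score table")
    week_start = _iso_week_start(scores["pred_time"])
    weekly = (
        scores.assign(week_start=week_start)
        .groupby("week_start")
        .agg(
            n=("crps_model", "size"),
            mean_crps_model=("crps_model", "mean"),
            mean_crps_baseline=("crps_baseline", "mean"),
        )
        .reset_index()
        .sort_values("week_start")
        .reset_index(drop=True)
    )
    weekly["ratio"] = weekly["mean_crps_model"] / weekly["mean_crps_baseline"]
    epoch = weekly["week_start"].iloc[0]
    weekly["week_index"] = ((weekly["week_start"] - epoch).dt.days // 7).astype(int)
    if len(weekly) < 3:
        raise DataError(
            f"need scores spanning >= 3 ISO weeks for the drift regression, "
            f"got {len(weekly)}"
        )
    res = sm.OLS(weekly["ratio"].to_numpy(),
                 sm.add_constant(weekly["week_index"].to_numpy())).fit()
    lo, hi = np.asarray(res.conf_int(alpha=0.05))[1]
    return DriftResult(
        weekly=weekly,
        slope=float(res.params[1]),
        slope_ci=(float(lo), float(hi)),
        intercept=float(res.params[0]),
        n_weeks=int(len(weekly)),
    )


# ===================================================================== #
# retraining comparison
# ===================================================================== #

@dataclass
class RetrainPlan:
    """Training windows for the primary and secondary (proximal) models and
    the later comparison window; all half-open ``[start, end)`` date pairs."""

    primary_window: tuple
    secondary_window: tuple
    comparison_window: tuple

    def validate(self) -> "RetrainPlan":
        windows = {
            "primary_window": self.primary_window,
            "secondary_window": self.secondary_window,
            "comparison_window": self.comparison_window,
        }
        parsed = {}
        for name, (a, b) in windows.items():
            a, b = pd.Timestamp(a), pd.Timestamp(b)
            if not a < b:
                raise ConfigError(f"{name} start must precede its end")
            parsed[name] = (a, b)
        ca, _ = parsed["comparison_window"]
        for name in ("primary_window", "secondary_window"):
            _, b = parsed[name]
            if b > ca:
                raise ConfigError(
                    f"comparison_window must follow and not overlap {name}"
                )
        return self


def _window_mask(cases: pd.DataFrame, window) -> pd.Series:
    a, b = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return (cases["anaesthesia_start"] >= a) & (cases["anaesthesia_start"] < b)


def run_retrain_comparison(plan: RetrainPlan, cases: pd.DataFrame,
                           observations: pd.DataFrame, spec: ModelSpec,
                           window=None, min_count: int = 2,
                           lookback: float = 120.0) -> dict:
    """Train primary and secondary models per the plan; compare on the
    comparison window.

    Each model builds its own vocabulary and baseline from its own training
    window (a retrained deployment would).  Returns per-model mean CRPS with
    naive standard errors and the paired per-prediction CRPS difference
    (secondary minus primary; negative means the proximal model is better).
    """
    plan.validate()
    out = {}
    obs_by_case = observations
    comp_cases = cases[_window_mask(cases, plan.comparison_window)]
    if len(comp_cases) == 0:
        raise DataError("no cases in the comparison window")
    comp_obs = obs_by_case[obs_by_case["case_id"].isin(set(comp_cases["case_id"]))]

    per_model = {}
    for name, train_window in (
        ("primary", plan.primary_window),
        ("secondary", plan.secondary_window),
    ):
        train_cases = cases[_window_mask(cases, train_window)]
        if len(train_cases) < 2:
            raise DataError(f"not enough cases in the {name} training window")
        train_obs = obs_by_case[
            obs_by_case["case_id"].isin(set(train_cases["case_id"]))
        ]
        vocab = build_vocab(train_cases, train_obs, min_count=min_count)
        model = train_model(
            snapshot_stream(train_cases, train_obs, vocab,
                            window=window, lookback=lookback),
            spec, vocab,
        )
        baseline = fit_baseline(train_cases)
        preds = model.predict_batch(
            snapshot_stream(comp_cases, comp_obs, vocab,
                            window=window, lookback=lookback)
        )
        per_model[name] = score_predictions(preds, comp_cases, baseline)

    sp, ss = per_model["primary"], per_model["secondary"]
    if len(sp) != len(ss) or not (sp["case_id"].to_numpy() == ss["case_id"].to_numpy()).all():
        raise DataError("primary and secondary predictions are not aligned")
    diff = ss["crps_model"].to_numpy() - sp["crps_model"].to_numpy()
    n = len(diff)
    for name, s in per_model.items():
        out[f"{name}_mean_crps"] = float(s["crps_model"].mean())
        out[f"{name}_se"] = float(s["crps_model"].std() / np.sqrt(n))
    out["mean_diff"] = float(diff.mean())
    out["diff_se"] = float(diff.std() / np.sqrt(n)) if n > 1 else 0.0
    # case-clustered alternative: minutes of one case share its outcome, so
    # the per-prediction se understates the paired uncertainty
    by_case = pd.Series(diff).groupby(sp["case_id"].to_numpy()).mean()
    out["diff_se_by_case"] = (
        float(by_case.std() / np.sqrt(len(by_case))) if len(by_case) > 1 else 0.0
    )
    out["n_predictions"] = int(n)
    out["n_cases"] = int(comp_cases["case_id"].nunique())
    return out
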