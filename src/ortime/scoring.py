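"""CRPS scoring and stratified aggregation.

The continuous ranked probability score of a forecast CDF ``F`` at outcome
``y`` is ``crps(F, y) = integral (F(x) - 1{x >= y})^2 dx``.  For the binned
forecasts produced here (point masses ``p_k`` at bin midpoints ``x_k``) the
integral is piecewise constant and has the exact closed form

    crps = sum_k p_k |x_k - y|  -  1/2 sum_jk p_j p_k |x_j - x_k|,

the discrete energy form of the score.  For a deterministic forecast the
score reduces to absolute error.  CRPS is translation invariant, so the
remaining-duration histogram at elapsed minute ``t`` scores identically to
the total-duration histogram shifted by ``t``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .models import BaselineDurationRegressor, DurationDistribution, Predictions, apply_baseline

#: Scheduled-duration stratum edges, minutes.
SCHEDULED_BIN_EDGES = (0.0, 60.0, 120.0, 240.0, np.inf)
#: Width of percentage-elapsed strata.
PCT_BIN_WIDTH = 5.0

STRATIFIERS = ("month", "hospital", "service", "sched_bin", "pct_bin")


def crps_points(points: np.ndarray, probs: np.ndarray, y: float) -> float:
    """Exact CRPS of a discrete forecast with mass ``probs`` at ``points``."""
    points = np.asarray(points, dtype=float)
    probs = np.asarray(probs, dtype=float)
    term1 = float(probs @ np.abs(points - y))
    term2 = 0.5 * float(probs @ np.abs(points[:, None] - points[None, :]) @ probs)
    return term1 - term2


def crps(dist: DurationDistribution, y: float) -> float:
    """CRPS of a binned duration forecast at outcome ``y`` (minutes)."""
    y = float(y)
    if not np.isfinite(y) or y < 0:
        raise DataError(f"outcome y must be a finite nonnegative duration, got {y}")
    return crps_points(dist.points, dist.probs, y)


def crps_point(forecast: float, y: float) -> float:
    """CRPS of a deterministic forecast: absolute error, minutes."""
    return float(abs(float(forecast) - float(y)))


def crps_batch(probs: np.ndarray, points: np.ndarray, y: np.ndarray,
               chunk: int = 65536) -> np.ndarray:
    """Vectorized CRPS for many forecasts sharing one bin grid."""
    probs = np.asarray(probs, dtype=np.float64)
    points = np.asarray(points, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.abs(points[:, None] - points[None, :])
    out = np.empty(len(y))
    for lo in range(0, len(y), chunk):
        p = probs[lo:lo + chunk]
        yy = y[lo:lo + chunk, None]
        term1 = (p * np.abs(points[None, :] - yy)).sum(axis=1)
        term2 = 0.5 * ((p @ D) * p).sum(axis=1)
        out[lo:lo + chunk] = term1 - term2
    return out


# ===================================================================== #
# score tables
# ===================================================================== #

def score_predictions(predictions: Predictions, cases: pd.DataFrame,
                      baseline: BaselineDurationRegressor) -> pd.DataFrame:
    """One score record per prediction.

    The model forecast is scored as a distribution; the benchmark is the
    bias-corrected scheduled duration scored as a point forecast, constant
    over all minutes of a case.  Raises :class:`DataError` for predictions
    whose ``case_id`` has no row in ``cases``.
    """
    case_ids = np.asarray(predictions.case_id)
    lookup = cases.set_index("case_id")
    missing = sorted(set(case_ids) - set(lookup.index))
    if missing:
        raise DataError(f"orphan predictions for case_ids: {missing[:10]}")

    rows = lookup.loc[case_ids]
    y_remaining = predictions.label - predictions.t
    crps_model = crps_batch(predictions.probs, predictions.points, y_remaining)
    corrected = apply_baseline(baseline, rows["scheduled_duration"].to_numpy())
    crps_base = np.abs(corrected - predictions.label)

    scores = pd.DataFrame(
        {
            "case_id": case_ids,
            "t": predictions.t,
            "pred_time": pd.DatetimeIndex(predictions.pred_time),
            "pct_elapsed": 100.0 * predictions.t / predictions.label,
            "crps_model": crps_model,
            "crps_baseline": crps_base,
            "hospital": rows["hospital"].to_numpy(),
            "service": rows["service"].to_numpy(),
            "scheduled_duration": rows["scheduled_duration"].to_numpy(),
        }
    )
    scores["month"] = scores["pred_time"].dt.strftime("%Y-%m")
    scores["pct_elapsed"] = scores["pct_elapsed"].clip(upper=100.0)
    return scores


def _stratum(scores: pd.DataFrame, by: str) -> pd.Series:
    if by in ("month", "hospital", "service"):
        return scores[by]
    if by == "sched_bin":
        edges = list(SCHEDULED_BIN_EDGES)
        labels = [
            f"{int(a)}-{int(b)} min" if np.isfinite(b) else f"{int(a)}+ min"
            for a, b in zip(edges[:-1], edges[1:])
        ]
        return pd.cut(scores["scheduled_duration"], bins=edges, labels=labels,
                      right=False).astype(str)
    if by == "pct_bin":
        edges = np.arange(0.0, 100.0 + PCT_BIN_WIDTH, PCT_BIN_WIDTH)
        mid = (np.clip(np.digitize(scores["pct_elapsed"], edges[1:-1]), 0,
                       len(edges) - 2) + 0.5) * PCT_BIN_WIDTH
        return pd.Series(mid, index=scores.index, name="pct_bin")
    raise DataError(f"unknown stratifier {by!r}; expected one of {STRATIFIERS}")


def aggregate(scores: pd.DataFrame, by: str, min_n: int = 1) -> pd.DataFrame:
    """Per-stratum prediction counts, mean CRPS, naive se and CRPS ratio.

    ``se`` is sd/sqrt(n) over predictions, mirroring the convention of
    reporting per-prediction standard errors without a within-case
    correlation correction.  Strata with fewer than ``min_n`` predictions
    are excluded.
    """
    if len(scores) == 0:
        raise DataError("empty score table")
    g = scores.groupby(_stratum(scores, by), observed=True)
    out = g.agg(
        n=("crps_model", "size"),
        mean_crps_model=("crps_model", "mean"),
        sd_model=("crps_model", "std"),
        mean_crps_baseline=("crps_baseline", "mean"),
        sd_baseline=("crps_baseline", "std"),
    ).reset_index(names="stratum")
    out["se_model"] = (out["sd_model"] / np.sqrt(out["n"])).fillna(0.0)
    out["se_baseline"] = (out["sd_baseline"] / np.sqrt(out["n"])).fillna(0.0)
    out["ratio"] = out["mean_crps_model"] / out["mean_crps_baseline"]
    out = out[out["n"] >= min_n].reset_index(drop=True)
    return out[
        ["stratum", "n", "mean_crps_model", "se_model",
         "mean_crps_baseline", "se_baseline", "ratio"]
    ]


def summarize(scores: pd.DataFrame) -> dict:
    """Global per-prediction means, naive standard errors and ratio."""
    n = len(scores)
    if n == 0:
        raise DataError("empty score table")
    return {
        "n_predictions": int(n),
        "n_cases": int(scores["case_id"].nunique()),
        "mean_crps_model": float(scores["crps_model"].mean()),
        "se_crps_model": float(scores["crps_model"].std() / np.sqrt(n)),
        "mean_crps_baseline": float(scores["crps_baseline"].mean()),
        "se_crps_baseline": float(scores["crps_baseline"].std() / np.sqrt(n)),
        "crps_ratio": float(scores["crps_model"].mean()
                            / scores["crps_baseline"].mean()),
    }
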