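"""Probabilistic duration models.

Two predictors are defined:

* :class:`BaselineDurationRegressor` — the bias-corrected scheduled-duration
  benchmark: ordinary least squares of actual on scheduled duration, fitted
  on training-window cases, applied as a point forecast (constant over the
  whole case).

* :class:`HistogramDurationNet` — a feed-forward network mapping a snapshot
  feature vector to a histogram over *remaining* duration (geometric bins),
  trained with a discretized-CRPS loss (or cross-entropy).  Shifting the
  remaining-duration bins by the elapsed time ``t`` gives the distribution
  over total duration, whose support therefore starts at ``t``: no
  probability mass on totals shorter than the time already elapsed.

Both follow the scikit-learn estimator protocol (``fit``, ``predict`` /
``predict_proba``, ``get_params``); :func:`train_model` / :func:`fit_baseline`
are thin task-level wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .config import ModelSpec
from .errors import DataError
from .features import SnapshotVectorizer, featurize
from .replay import Snapshot, Vocabulary


# ===================================================================== #
# output distribution
# ===================================================================== #

@dataclass
class DurationDistribution:
    """A discrete forecast over duration bins.

    ``bin_edges`` has length K+1 and is strictly increasing; ``probs`` has
    length K, is nonnegative and sums to one.  The forecast is treated as
    point masses at the bin midpoints for scoring.
    """

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.probs) + 1:
            raise DataError("bin_edges must have length len(probs) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise DataError("bin_edges must be strictly increasing")
        if np.any(self.probs < -1e-12):
            raise DataError("probs must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise DataError("probs must sum to 1 within 1e-6")

    @property
    def points(self) -> np.ndarray:
        """Bin midpoints carrying the probability mass."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        return float(self.points @ self.probs)

    def cdf(self, x) -> np.ndarray:
        """Step CDF of the point-mass representation."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self.probs)])
        return cum[np.searchsorted(self.points, x, side="right")]

    def shift(self, delta: float) -> "DurationDistribution":
        return DurationDistribution(self.bin_edges + delta, self.probs)


def remaining_bin_edges(n_bins: int = 128, max_minutes: float = 1440.0) -> np.ndarray:
    """Geometric bin edges over remaining duration: [0, 1, ..., max]."""
    if n_bins < 2:
        raise DataError("n_bins must be >= 2")
    return np.concatenate([[0.0], np.geomspace(1.0, max_minutes, n_bins)])


# ===================================================================== #
# baseline
# ===================================================================== #

class BaselineDurationRegressor(RegressorMixin, BaseEstimator):
    """Bias-corrected scheduled duration: OLS of actual on scheduled.

    Fitted attributes: ``slope_``, ``intercept_`` and their standard errors
    ``slope_se_``, ``intercept_se_``.  Predictions are floored at 1 minute.
    """

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float).reshape(-1, 1), y)
        if len(y) < 2:
            raise DataError("need at least 2 cases to fit the baseline")
        if np.ptp(X[:, 0]) == 0:
            raise DataError("degenerate design: scheduled duration is constant")
        res = sm.OLS(y, sm.add_constant(X[:, 0])).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.intercept_se_ = float(res.bse[0])
        self.slope_se_ = float(res.bse[1])
        self.n_cases_ = int(len(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = check_array(np.asarray(X, dtype=float).reshape(-1, 1))
        return np.maximum(self.slope_ * X[:, 0] + self.intercept_, 1.0)

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope": self.slope_, "intercept": self.intercept_,
            "slope_se": self.slope_se_, "intercept_se": self.intercept_se_,
            "n_cases": self.n_cases_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineDurationRegressor":
        m = cls()
        m.slope_ = float(d["slope"])
        m.intercept_ = float(d["intercept"])
        m.slope_se_ = float(d.get("slope_se", np.nan))
        m.intercept_se_ = float(d.get("intercept_se", np.nan))
        m.n_cases_ = int(d.get("n_cases", 0))
        return m


def fit_baseline(cases: pd.DataFrame) -> BaselineDurationRegressor:
    """Fit the benchmark on a training-window case table."""
    return BaselineDurationRegressor().fit(
        cases["scheduled_duration"].to_numpy(),
        cases["actual_duration"].to_numpy(),
    )


def apply_baseline(model: BaselineDurationRegressor, scheduled_duration):
    """Bias-corrected scheduled duration, floored at 1 minute."""
    scalar = np.isscalar(scheduled_duration)
    out = model.predict(np.atleast_1d(scheduled_duration))
    return float(out[0]) if scalar else out


# ===================================================================== #
# histogram network
# ===================================================================== #

class HistogramDurationNet(BaseEstimator):
    """Feed-forward histogram forecaster over remaining duration.

    A fully-connected ReLU network with a softmax head over ``n_bins``
    geometric duration bins.  The default loss is the discretized CRPS of
    the predicted histogram against the observed remaining duration —
    training directly on the evaluation metric; ``loss="xent"`` trains on
    the cross-entropy of the label's bin instead.  Optimisation is Adam on
    shuffled minibatches; everything is seeded, so training is bit-for-bit
    reproducible single-threaded.
    """

    def __init__(self, n_bins: int = 128, max_minutes: float = 1440.0,
                 hidden: tuple = (96, 96), loss: str = "crps", lr: float = 1e-3,
                 epochs: int = 10, batch_size: int = 512, l2: float = 0.2,
                 seed: int = 0, verbose: int = 0):
        self.n_bins = n_bins
        self.max_minutes = max_minutes
        self.hidden = hidden
        self.loss = loss
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.l2 = l2
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.loss not in ("crps", "xent"):
            raise DataError("loss must be 'crps' or 'xent'")
        if y.min() < 0:
            raise DataError("remaining durations must be nonnegative")
        if y.max() > self.max_minutes:
            raise DataError(
                f"max_minutes={self.max_minutes} is smaller than the longest "
                f"training remaining duration ({y.max():.1f} min)"
            )
        rng = np.random.default_rng(int(self.seed) & 0x7FFFFFFF)
        self.edges_ = remaining_bin_edges(self.n_bins, self.max_minutes)
        self.points_ = 0.5 * (self.edges_[:-1] + self.edges_[1:])
        K = self.n_bins

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 1e-9, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_

        sizes = [X.shape[1], *self.hidden, K]
        W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
             for i in range(len(sizes) - 1)]
        b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

        if self.loss == "xent":
            ybin = np.clip(np.searchsorted(self.edges_, y, side="right") - 1, 0, K - 1)
        else:
            # pairwise |x_i - x_j| between bin points, for the CRPS gradient
            D = np.abs(self.points_[:, None] - self.points_[None, :])

        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(y)
        bs = min(self.batch_size, n)
        self.history_ = []

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                xb = Xs[idx]
                # forward
                acts = [xb]
                h = xb
                for i in range(len(W) - 1):
                    h = np.maximum(h @ W[i] + b[i], 0.0)
                    acts.append(h)
                z = h @ W[-1] + b[-1]
                z -= z.max(axis=1, keepdims=True)
                ez = np.exp(z)
                p = ez / ez.sum(axis=1, keepdims=True)

                if self.loss == "xent":
                    lossb = -np.log(p[np.arange(len(idx)), ybin[idx]] + 1e-12)
                    dz = p.copy()
                    dz[np.arange(len(idx)), ybin[idx]] -= 1.0
                else:
                    yb = y[idx][:, None]
                    absdiff = np.abs(self.points_[None, :] - yb)
                    pD = p @ D
                    lossb = (p * absdiff).sum(1) - 0.5 * (pD * p).sum(1)
                    g = absdiff - pD  # d loss / d p
                    dz = p * (g - (p * g).sum(1, keepdims=True))
                dz /= len(idx)
                epoch_loss += float(lossb.sum())
                seen += len(idx)

                # backward
                step += 1
                grads_W, grads_b = [None] * len(W), [None] * len(W)
                delta = dz
                for i in range(len(W) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta + self.l2 * W[i]
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ W[i].T) * (acts[i] > 0)
                corr1 = 1.0 - beta1 ** step
                corr2 = 1.0 - beta2 ** step
                for i in range(len(W)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * grads_W[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * grads_W[i] ** 2
                    W[i] -= self.lr * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
                    mb[i] = beta1 * mb[i] + (1 - beta1) * grads_b[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * grads_b[i] ** 2
                    b[i] -= self.lr * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)
            self.history_.append(epoch_loss / max(seen, 1))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}: loss {self.history_[-1]:.3f}")

        self.W_ = W
        self.b_ = b
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------------ #

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "W_")
        X = check_array(X)
        h = (X - self.mean_) / self.scale_
        for i in range(len(self.W_) - 1):
            h = np.maximum(h @ self.W_[i] + self.b_[i], 0.0)
        z = h @ self.W_[-1] + self.b_[-1]
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Expected remaining duration, minutes."""
        return self.predict_proba(X) @ self.points_


# ===================================================================== #
# snapshot-level wrapper
# ===================================================================== #

@dataclass
class Predictions:
    """Vectorized per-snapshot forecasts plus join keys for scoring."""

    case_id: np.ndarray
    t: np.ndarray
    pred_time: np.ndarray
    label: np.ndarray
    scheduled_duration: np.ndarray
    probs: np.ndarray  # (n, K) over remaining-duration bins
    points: np.ndarray  # (K,) remaining-duration bin midpoints
    edges: np.ndarray  # (K+1,) remaining-duration bin edges

    def __len__(self) -> int:
        return len(self.t)

    def distribution(self, i: int) -> DurationDistribution:
        """Total-duration forecast for prediction ``i`` (support starts at t)."""
        return DurationDistribution(self.edges + float(self.t[i]), self.probs[i])


class DurationModel:
    """A trained duration predictor bound to its vocabulary and vectorizer."""

    def __init__(self, vectorizer: SnapshotVectorizer, net: HistogramDurationNet,
                 spec: ModelSpec, vocab_digest: str):
        self.vectorizer = vectorizer
        self.net = net
        self.spec = spec
        self.vocab_digest = vocab_digest

    def _check_vocab(self, vocab: Optional[Vocabulary]) -> None:
        if vocab is not None and vocab.digest() != self.vocab_digest:
            raise DataError(
                "vocabulary mismatch: snapshots were tokenized with a different "
                "vocabulary than the model was trained on"
            )

    def predict(self, snapshot: Snapshot,
                vocab: Optional[Vocabulary] = None) -> DurationDistribution:
        """Total-duration forecast for one snapshot.

        The histogram is over remaining duration shifted by the snapshot's
        elapsed time, so no mass lies below ``t`` by construction.
        """
        self._check_vocab(vocab)
        X = self.vectorizer.transform([snapshot])
        probs = self.net.predict_proba(X)[0]
        return DurationDistribution(self.net.edges_ + float(snapshot.t), probs)

    def predict_batch(self, snapshots: Iterable[Snapshot],
                      vocab: Optional[Vocabulary] = None,
                      chunk: int = 8192) -> Predictions:
        self._check_vocab(vocab)
        X, _, meta = featurize(
            snapshots, self.vectorizer.vocab,
            trend_window=self.vectorizer.trend_window,
        )
        probs = np.empty((len(X), self.net.n_bins), dtype=np.float32)
        for lo in range(0, len(X), chunk):
            probs[lo:lo + chunk] = self.net.predict_proba(X[lo:lo + chunk])
        return Predictions(
            case_id=meta["case_id"], t=meta["t"], pred_time=meta["pred_time"],
            label=meta["label"], scheduled_duration=meta["scheduled_duration"],
            probs=probs, points=self.net.points_, edges=self.net.edges_,
        )

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Single-file checkpoint: weights + spec + vocabulary digest."""
        arrays = {f"W{i}": w for i, w in enumerate(self.net.W_)}
        arrays.update({f"b{i}": x for i, x in enumerate(self.net.b_)})
        arrays["mean"] = self.net.mean_
        arrays["scale"] = self.net.scale_
        meta = {
            "format_version": 1,
            "spec": self.spec.to_dict(),
            "vocab_digest": self.vocab_digest,
            "n_layers": len(self.net.W_),
            "n_features_in": self.net.n_features_in_,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, vocab: Vocabulary) -> "DurationModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = ModelSpec.from_dict(meta["spec"])
            net = _net_from_spec(spec)
            net.edges_ = remaining_bin_edges(spec.n_bins, spec.max_minutes)
            net.points_ = 0.5 * (net.edges_[:-1] + net.edges_[1:])
            net.W_ = [data[f"W{i}"] for i in range(meta["n_layers"])]
            net.b_ = [data[f"b{i}"] for i in range(meta["n_layers"])]
            net.mean_ = data["mean"]
            net.scale_ = data["scale"]
            net.n_features_in_ = meta["n_features_in"]
        if vocab.digest() != meta["vocab_digest"]:
            raise DataError("vocabulary mismatch: checkpoint was trained with a "
                            "different vocabulary")
        vec = SnapshotVectorizer(vocab=vocab, trend_window=spec.trend_window).fit()
        return cls(vec, net, spec, meta["vocab_digest"])


def _net_from_spec(spec: ModelSpec) -> HistogramDurationNet:
    return HistogramDurationNet(
        n_bins=spec.n_bins, max_minutes=spec.max_minutes, hidden=spec.hidden,
        loss=spec.loss, lr=spec.lr, epochs=spec.epochs,
        batch_size=spec.batch_size, l2=spec.l2, seed=spec.seed,
    )


def train_model(snapshots: Iterable[Snapshot], spec: ModelSpec,
                vocab: Vocabulary) -> DurationModel:
    """Train the duration network on training-window snapshots."""
    spec.validate()
    X, y, _ = featurize(snapshots, vocab, trend_window=spec.trend_window)
    if len(X) == 0:
        raise DataError("no training snapshots")
    net = _net_from_spec(spec).fit(X, y)
    vec = SnapshotVectorizer(vocab=vocab, trend_window=spec.trend_window).fit()
    return DurationModel(vec, net, spec, vocab.digest())
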