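"""Generative LDA trained from per-window embolism counts (weak supervision).

No hit-level labels exist in a combined AE/µCT experiment: the scanner only
says how many vessels emptied inside each time window.  The classifier is
two-class LDA — embolism features ~ N(µ1, Σ), background ~ N(µ0, Σ) — whose
parameters are estimated from window summaries:

* µ1 is the average of the window mean feature vectors weighted by each
  window's µCT count n1_d; µ0 the same weighted by the complement
  n0_d = m_d − n1_d (non-embolism hits are not observed separately, so the
  complement count is the only available weight);
* Σ is the window-size-weighted average of the within-window covariances;
* the class prior is the global count ratio Σn1 / Σm.

This estimator is deliberately the simple weighted-moment one: when windows
mix both classes the window means shrink the class means toward each other,
which is why per-hit embolism probabilities stay well below 1 in practice.
An optional moment-corrected variant (``moment_corrected=True``) solves the
two-point mixture moment equations instead and is unbiased under the
generative model; it is off by default.

Posteriors follow Bayes' rule with the two normal likelihoods, computed via
log-density differences; summing a window's posteriors gives its expected
embolism count, and leave-one-window-out refitting yields the observed vs
predicted count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .explore import ROCCurve, roc_from_values
from .ingest import FEATURE_COLUMNS, LabeledWindow

logger = logging.getLogger(__name__)

#: Relative ridge added to Σ's diagonal when it is near-singular.
RIDGE_EPS = 1e-8


@dataclass
class LDAModel:
    """Two-class shared-covariance Gaussian classifier."""

    mu0: np.ndarray
    mu1: np.ndarray
    sigma: np.ndarray
    prior1: float
    feature_names: tuple = FEATURE_COLUMNS
    regularized: bool = False

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not 0.0 < self.prior1 < 1.0:
            raise ValueError("prior1 must lie strictly inside (0, 1)")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")

    def _cho(self):
        try:
            return cho_factor(self.sigma)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("covariance is singular even after regularization") from exc

    def log_odds(self, x) -> np.ndarray:
        """log P(Y=1|x) − log P(Y=0|x); affine in x for shared covariance."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        cho = self._cho()
        d = cho_solve(cho, self.mu1 - self.mu0)
        mid = 0.5 * (self.mu0 + self.mu1)
        return np.log(self.prior1 / (1.0 - self.prior1)) + (x - mid) @ d

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0.tolist(),
            "mu1": self.mu1.tolist(),
            "sigma": self.sigma.tolist(),
            "prior1": float(self.prior1),
            "feature_names": list(self.feature_names),
            "regularized": bool(self.regularized),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            mu0=np.array(d["mu0"]),
            mu1=np.array(d["mu1"]),
            sigma=np.array(d["sigma"]),
            prior1=d["prior1"],
            feature_names=tuple(d.get("feature_names", FEATURE_COLUMNS)),
            regularized=d.get("regularized", False),
        )


@dataclass
class _WindowStats:
    """Sufficient statistics per window for weighted-moment fitting."""

    m: np.ndarray        # window sizes
    n1: np.ndarray       # µCT counts
    mean: np.ndarray     # (W, p) window mean feature vectors
    scatter: np.ndarray  # (W, p, p) within-window scatter: m_d * S_d (ddof 0)


def _window_stats(windows: list[LabeledWindow], features: np.ndarray) -> _WindowStats:
    p = features.shape[1]
    W = len(windows)
    m = np.zeros(W)
    n1 = np.zeros(W)
    mean = np.zeros((W, p))
    scatter = np.zeros((W, p, p))
    for i, w in enumerate(windows):
        if w.embolism_count > w.size:
            raise ValueError(
                f"window {w.index}: count {w.embolism_count} exceeds its size {w.size}"
            )
        m[i] = w.size
        n1[i] = w.embolism_count
        if w.size:
            x = features[w.signal_indices]
            mean[i] = x.mean(axis=0)
            dx = x - mean[i]
            scatter[i] = dx.T @ dx
    return _WindowStats(m=m, n1=n1, mean=mean, scatter=scatter)


def _fit_from_stats(
    stats: _WindowStats,
    exclude: int | None = None,
    ridge: float = RIDGE_EPS,
    covariance_weighting: str = "size",
    moment_corrected: bool = False,
) -> LDAModel:
    keep = np.ones(len(stats.m), dtype=bool)
    if exclude is not None:
        keep[exclude] = False
    keep &= stats.m > 0
    m, n1, mean, scatter = stats.m[keep], stats.n1[keep], stats.mean[keep], stats.scatter[keep]
    n0 = m - n1
    if n1.sum() == 0:
        raise ValueError("all window counts are zero: cannot estimate the embolism class")
    if n0.sum() == 0:
        raise ValueError("every hit is counted as embolism: cannot estimate the background class")

    if moment_corrected:
        # solve  mean_d ≈ (1 − π_d)·µ0 + π_d·µ1  by weighted least squares
        pi = n1 / m
        A = np.column_stack([1.0 - pi, pi])
        wts = np.sqrt(m)
        coef, *_ = np.linalg.lstsq(A * wts[:, None], mean * wts[:, None], rcond=None)
        mu0, mu1 = coef[0], coef[1]
    else:
        mu1 = (n1[:, None] * mean).sum(axis=0) / n1.sum()
        mu0 = (n0[:, None] * mean).sum(axis=0) / n0.sum()

    if covariance_weighting == "size":
        sigma = scatter.sum(axis=0) / m.sum()
    elif covariance_weighting == "class":
        with np.errstate(invalid="ignore", divide="ignore"):
            s_d = scatter / m[:, None, None]
        sigma = 0.5 * (
            (n1[:, None, None] * s_d).sum(axis=0) / n1.sum()
            + (n0[:, None, None] * s_d).sum(axis=0) / n0.sum()
        )
    else:
        raise ValueError("covariance_weighting must be 'size' or 'class'")

    if moment_corrected:
        # remove the between-class inflation mixed windows leave in the
        # within-window scatter: S_d = Σ + π_d(1−π_d)·δδᵀ under the model
        pi = n1 / m
        delta = mu1 - mu0
        infl = float((m * pi * (1.0 - pi)).sum() / m.sum())
        sigma = sigma - infl * np.outer(delta, delta)

    regularized = False
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > 1e12:
        sigma = sigma + ridge * np.trace(sigma) / sigma.shape[0] * np.eye(sigma.shape[0])
        regularized = True
        eigvals = np.linalg.eigvalsh(sigma)
        if eigvals[0] <= 0:  # still singular: escalate the ridge deterministically
            sigma = sigma + (abs(eigvals[0]) + 1e-6 * np.trace(sigma)) * np.eye(sigma.shape[0])

    prior1 = float(n1.sum() / m.sum())
    return LDAModel(mu0=mu0, mu1=mu1, sigma=sigma, prior1=prior1, regularized=regularized)


def fit_weighted_lda(
    windows: list[LabeledWindow],
    features: np.ndarray,
    ridge: float = RIDGE_EPS,
    covariance_weighting: str = "size",
    moment_corrected: bool = False,
) -> LDAModel:
    """Fit LDA from window-level counts.

    With every window pure (count 0 or count = size) this reduces exactly to
    supervised LDA fitted on pooled labels.  Raises if no window carries a
    positive count, or a count exceeds its window's size.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows to fit")
    stats = _window_stats(windows, np.asarray(features, dtype=float))
    return _fit_from_stats(
        stats,
        ridge=ridge,
        covariance_weighting=covariance_weighting,
        moment_corrected=moment_corrected,
    )


def posterior(model: LDAModel, x) -> np.ndarray:
    """P(embolism | features) via Bayes' rule with the two normal likelihoods.

    Computed from the log-density difference (the shared covariance cancels
    the quadratic terms), numerically stable for extreme feature values.
    Accepts a single 6-vector or an (n, 6) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    odds = model.log_odds(np.atleast_2d(x)).reshape(-1)
    p = np.exp(-np.logaddexp(0.0, -odds))  # sigmoid, stable for any magnitude
    return float(p[0]) if single else p


def predict_window_count(model: LDAModel, window: LabeledWindow, features: np.ndarray) -> float:
    """Expected embolism count of a window: the sum of its hits' posteriors."""
    if window.size == 0:
        return 0.0
    return float(np.sum(posterior(model, np.asarray(features)[window.signal_indices])))


@dataclass
class LOOResult:
    table: pd.DataFrame            # window, kind, size, observed, predicted, flagged
    observed_total: float
    predicted_total: float
    models: list = field(default_factory=list, repr=False)


def loo_crossvalidate(
    windows: list[LabeledWindow],
    features: np.ndarray,
    ridge: float = RIDGE_EPS,
    covariance_weighting: str = "size",
    moment_corrected: bool = False,
    keep_models: bool = False,
) -> LOOResult:
    """Leave-one-window-out validation of predicted vs observed counts.

    For each window a model is trained on all remaining windows and its
    posterior sum on the held-out window recorded.  A training fold without
    any positive count cannot identify the embolism class; such folds are
    flagged and fall back to the global count prior (predicted = prior × size)
    with a logged warning.
    """
    if len(windows) < 3:
        raise ValueError("need at least three windows for leave-one-out validation")
    features = np.asarray(features, dtype=float)
    stats = _window_stats(windows, features)
    global_prior = float(stats.n1.sum() / stats.m.sum()) if stats.m.sum() else 0.0

    rows = []
    models = []
    for i, w in enumerate(windows):
        flagged = False
        try:
            model = _fit_from_stats(
                stats,
                exclude=i,
                ridge=ridge,
                covariance_weighting=covariance_weighting,
                moment_corrected=moment_corrected,
            )
            predicted = predict_window_count(model, w, features)
        except ValueError:
            logger.warning(
                "window %s: training fold has no positive counts; falling back to the global prior",
                w.index,
            )
            flagged = True
            model = None
            predicted = global_prior * w.size
        if keep_models:
            models.append(model)
        rows.append(
            {
                "window": w.index,
                "kind": w.kind,
                "size": w.size,
                "observed": w.embolism_count,
                "predicted": predicted,
                "flagged": flagged,
            }
        )
    table = pd.DataFrame(rows)
    return LOOResult(
        table=table,
        observed_total=float(table["observed"].sum()),
        predicted_total=float(table["predicted"].sum()),
        models=models,
    )


def roc_lda(
    windows: list[LabeledWindow], posteriors: np.ndarray, capped: bool = True
) -> ROCCurve:
    """ROC over descending posterior cutoffs, capped within windows.

    Uses the same count-supervised true/false-positive construction as the
    single-parameter ROC curves, so the curves are directly comparable.
    """
    return roc_from_values(np.asarray(posteriors, dtype=float), windows, capped=capped)
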