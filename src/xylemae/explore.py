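"""Unsupervised structure and static-threshold screening of AE parameters.

Before any classifier is trained it is worth asking whether single waveform
parameters already separate embolism hits from the rest: PCA shows which
parameters carry the variance, the correlogram which ones are redundant, and
per-parameter ROC curves whether any static threshold can recover the number
of embolisms the scanner counted.

Because per-hit truth is unavailable in a real experiment — the labels are
per-window µCT counts — the true-positive count at a threshold is *capped*
within each window: of the hits retained above the threshold in window d, at
most count_d can be true embolisms.  With this construction the ROC of a
perfectly separating parameter rises to tpr = 1 at fpr = 0 exactly when the
retained totals match the µCT total.  The uncapped variant (every retained
hit in an embolism window counts as a potential true positive) is available
behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .ingest import PARAMETER_COLUMNS, TIME_COLUMN, LabeledWindow

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA and correlations
# ---------------------------------------------------------------------------

@dataclass
class PCASummary:
    loadings: np.ndarray              # (n_kept_columns, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray
    columns: list
    dropped: list = field(default_factory=list)


def pca_summary(features, columns=None, standardize: bool = True) -> PCASummary:
    """Principal components of the waveform-parameter matrix.

    Columns are standardized to unit variance first (the 18 parameters span
    several orders of magnitude across units); constant columns are dropped
    with a warning.  Explained-variance fractions sum to 1 and the loading
    matrix is orthonormal.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if columns is None:
        columns = [f"col{i}" for i in range(x.shape[1])]
    sd = x.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        logger.warning("dropping constant column(s) before PCA: %s", ", ".join(map(str, dropped)))
    x = x[:, keep]
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA()
    pca.fit(x)
    return PCASummary(
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        columns=[c for c, k in zip(columns, keep) if k],
        dropped=dropped,
    )


def correlation_matrix(signals: pd.DataFrame, columns=PARAMETER_COLUMNS) -> pd.DataFrame:
    """Pearson correlation matrix of the waveform parameters.

    Constant columns yield NaN rows/columns and are flagged with a warning
    rather than dropped, so the matrix keeps the full parameter layout.
    """
    df = signals[list(columns)]
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        logger.warning("correlation undefined for constant column(s): %s", ", ".join(constant))
    return df.corr(method="pearson")


# ---------------------------------------------------------------------------
# per-window histogram thresholding
# ---------------------------------------------------------------------------

def histogram_threshold(
    signals: pd.DataFrame, window: LabeledWindow, parameter: str
) -> tuple[float, np.ndarray]:
    """Upper-level threshold retaining exactly the window's µCT count of hits.

    Returns (threshold, retained positional indices): the ``embolism_count``
    hits with the largest parameter values are retained (ties broken in
    favour of earlier timestamps) and the threshold is the largest
    non-retained value — every retained value lies strictly above it except
    under exact ties, where the canonical retained set is still returned.
    A count of zero retains nothing and thresholds at the window maximum.
    """
    members = window.signal_indices
    k = window.embolism_count
    if k > len(members):
        raise ValueError(
            f"window {window.index}: embolism count {k} exceeds its {len(members)} hits"
        )
    values = signals[parameter].to_numpy()[members]
    times = signals[TIME_COLUMN].to_numpy()[members]
    order = np.lexsort((times, -values))  # by value desc, then time asc
    retained = members[order[:k]]
    if k == 0:
        threshold = float(values.max()) if len(values) else np.nan
    elif k < len(members):
        threshold = float(values[order[k]])
    else:
        threshold = -np.inf
    return threshold, np.sort(retained)


# ---------------------------------------------------------------------------
# ROC curves against window-level counts
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Threshold sweep of capped true/false-positive rates.

    ``thresholds`` descend from the global maximum (tpr = fpr = 0) to below
    the global minimum (tpr = fpr = 1); rates are non-decreasing along the
    sweep.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    positives_total: int
    negatives_total: int

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr})


def roc_from_values(values, windows: list[LabeledWindow], capped: bool = True) -> ROCCurve:
    """ROC over descending cutoffs of a per-hit score, supervised by counts.

    At cutoff t, window d retains the member hits with score > t; the capped
    true positives are min(retained_d, count_d) and the remainder are false
    positives.  tpr(t) = ΣTP/Σcount, fpr(t) = ΣFP/(N − Σcount), with N the
    number of windowed hits.
    """
    values = np.asarray(values, dtype=float)
    counts = np.array([w.embolism_count for w in windows])
    sizes = np.array([w.size for w in windows])
    positives = int(counts.sum())
    n_signals = int(sizes.sum())
    negatives = n_signals - positives
    if positives == 0:
        raise ValueError("all window counts are zero: no positives to rate")

    member_values = [values[w.signal_indices] for w in windows]
    all_values = np.concatenate([v for v in member_values if len(v)])
    thresholds = np.concatenate([np.unique(all_values)[::-1], [-np.inf]])

    tp = np.zeros(len(thresholds))
    fp = np.zeros(len(thresholds))
    for v, c in zip(member_values, counts):
        if not len(v):
            continue
        sv = np.sort(v)
        retained = len(sv) - np.searchsorted(sv, thresholds, side="right")
        if capped:
            tp_d = np.minimum(retained, c)
        else:
            tp_d = retained if c > 0 else np.zeros_like(retained)
        tp += tp_d
        fp += retained - tp_d

    pos_denom = positives if capped else int(sizes[counts > 0].sum())
    return ROCCurve(
        thresholds=thresholds,
        tpr=tp / max(pos_denom, 1),
        fpr=fp / max(negatives, 1),
        positives_total=positives,
        negatives_total=negatives,
    )


def roc_parameter(
    signals: pd.DataFrame, windows: list[LabeledWindow], parameter: str, capped: bool = True
) -> ROCCurve:
    """ROC curve of a single waveform parameter (e.g. AMP or FREQPP2)."""
    return roc_from_values(signals[parameter].to_numpy(), windows, capped=capped)
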