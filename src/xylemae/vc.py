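"""Vulnerability-curve construction and comparison.

A xylem vulnerability curve (VC) relates percentage embolism formation to
xylem water potential ψ_x (MPa).  Three acoustic/imaging routes to a VC are
supported: cumulative counts of µCT-detected embolisms, cumulative unfiltered
AE hits, and cumulative per-hit embolism probabilities from the classifier.
The time axis is converted to ψ_x through a three-segment linear stress–strain
model fitted between dendrometer shrinkage (strain, µm mm⁻¹) and point
measurements of ψ_x.

Conventions adopted where the procedure is under-determined:

* Cumulative series are evaluated as the exact time average of the running
  sum inside each 10-min bin (not a resample at bin ends).
* Derivatives are iterated windowed least-squares slopes (Savitzky–Golay with
  polynomial order 1), robust to bin noise; an order-k derivative is k
  applications of the windowed slope with the same window.
* Rescaling to percentage raises only the curve ceiling by the native
  (pre-existing) embolism count: end% = 100·(native + detected)/total, the
  curve running from 0 to end%.  The alternative convention that starts the
  curve at the native percentage is available behind ``start_at_native``.
* Vulnerability levels (12/50/88/100) are absolute percentages of the axis,
  not fractions of the ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cumulative curves
# ---------------------------------------------------------------------------

@dataclass
class CumulativeCurve:
    """Running sum of events (or probabilities) averaged per time bin."""

    bin_centers: np.ndarray  # seconds since experiment start
    values: np.ndarray
    bin_seconds: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("cumulative values must be non-decreasing")

    @property
    def final(self) -> float:
        return float(self.values[-1])


def cumulate(
    times,
    weights=None,
    bin_minutes: float = 10.0,
    span: tuple[float, float] | None = None,
) -> CumulativeCurve:
    """Cumulate events (unit weight) or probabilities over fixed time bins.

    Each bin's value is the exact time average of the running-sum step
    function inside the bin.  ``span`` fixes the covered interval in seconds;
    by default it runs from 0 to the last event, and an empty input with no
    span yields a single zero bin.
    """
    times = np.asarray(times, dtype=float)
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    if times.shape != weights.shape:
        raise ValueError("times and weights must have matching shapes")

    bw = bin_minutes * 60.0
    if span is None:
        t0 = 0.0
        t1 = float(times.max()) if times.size else bw
    else:
        t0, t1 = map(float, span)
    n_bins = max(1, int(np.ceil((t1 - t0) / bw)))
    edges = t0 + bw * np.arange(n_bins + 1)

    order = np.argsort(times, kind="stable")
    times, weights = times[order], weights[order]
    inside = (times >= t0) & (times < edges[-1])
    times, weights = times[inside], weights[inside]

    # value entering each bin = sum of weights before the bin's left edge
    csum = np.concatenate([[0.0], np.cumsum(weights)])
    at_edges = csum[np.searchsorted(times, edges[:-1], side="left")]
    # within-bin contribution to the time integral: each event adds its
    # weight from its timestamp to the bin's right edge
    idx = np.minimum(((times - t0) / bw).astype(int), n_bins - 1)
    integral = at_edges * bw + np.bincount(
        idx, weights=weights * (edges[idx + 1] - times), minlength=n_bins
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CumulativeCurve(bin_centers=centers, values=integral / bw, bin_seconds=bw)


@dataclass
class DerivativeCurve:
    bin_centers: np.ndarray
    values: np.ndarray
    bin_seconds: float
    order: int
    window_minutes: float


def moving_derivative(curve: CumulativeCurve, order: int, window_minutes: float) -> DerivativeCurve:
    """Order-th derivative as iterated centered windowed least-squares slopes.

    Each pass replaces the series by the slope of a straight line fitted over
    a centered moving window (``window_minutes`` wide); ``order`` passes give
    the order-th derivative in units of value·s⁻ᵒʳᵈᵉʳ.  Exact for polynomials
    up to the requested order.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    wbins = int(round(window_minutes * 60.0 / curve.bin_seconds))
    wbins = max(3, wbins + (1 - wbins % 2))  # odd, >= 3 bins
    if wbins > len(curve.values):
        raise ValueError(
            f"derivative window of {wbins} bins exceeds series length {len(curve.values)}"
        )
    y = curve.values.astype(float)
    for _ in range(order):
        y = savgol_filter(y, wbins, polyorder=1, deriv=1, delta=curve.bin_seconds, mode="interp")
    return DerivativeCurve(
        bin_centers=curve.bin_centers,
        values=y,
        bin_seconds=curve.bin_seconds,
        order=order,
        window_minutes=window_minutes,
    )


def find_endpoint(
    curve: CumulativeCurve,
    d1_window_minutes: float = 15.0,
    d3_window_minutes: float = 48 * 60.0,
) -> float | None:
    """Locate the endpoint of embolism-related AE, or ``None`` if not reached.

    The endpoint is the first local maximum of the third derivative of the
    cumulative curve occurring after the peak of AE activity (the maximum of
    the first derivative).  When the third derivative is still non-decreasing
    at the end of the series — dehydration was stopped before all conduits
    emptied — the endpoint is undefined and ``None`` is returned.
    """
    d1 = moving_derivative(curve, 1, d1_window_minutes)
    d3 = moving_derivative(curve, 3, d3_window_minutes)
    i_star = int(np.argmax(d1.values))
    v = d3.values
    for i in range(i_star + 1, len(v) - 1):
        if v[i] >= v[i - 1] and v[i] > v[i + 1]:
            return float(curve.bin_centers[i])
    return None


# ---------------------------------------------------------------------------
# percentage rescaling
# ---------------------------------------------------------------------------

def end_percentage(native_embolized: int, detected_end: float, total_vessels: int) -> tuple[float, int]:
    """Percentage ceiling of a VC given native and newly detected embolisms.

    Returns (exact, reported) where reported is rounded to the integer
    percentage used in summary tables, e.g. (541, 518, 1100) -> 96 and
    (541, 457, 1100) -> 91.
    """
    if total_vessels <= 0:
        raise ValueError("total_vessels must be positive")
    if native_embolized + detected_end > total_vessels + 1e-9:
        raise ValueError("native + detected embolisms exceed the vessel total")
    exact = 100.0 * (native_embolized + detected_end) / total_vessels
    return exact, int(round(exact))


@dataclass
class VulnerabilityCurve:
    """Percentage embolism versus xylem water potential (MPa, decreasing)."""

    psi: np.ndarray
    percent: np.ndarray
    end_percent: float

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if self.psi.shape != self.percent.shape:
            raise ValueError("psi and percent must have matching shapes")


def rescale_percentage(
    curve: CumulativeCurve,
    native_embolized: int,
    detected_end: float | None = None,
    total_vessels: int = 1100,
    start_at_native: bool = False,
) -> tuple[np.ndarray, float]:
    """Convert a cumulative curve to percentage embolism.

    ``detected_end`` defaults to the curve's final value (appropriate when the
    curve cumulates detected events); pass the classifier's detected total
    when rescaling a probability curve.  The native count raises the ceiling:
    the percentage axis runs 0 → end% with end% = 100·(native + detected)/total.
    With ``start_at_native`` the curve instead runs native% → end%.
    """
    if curve.final <= 0:
        raise ValueError("cumulative curve must end above zero to be rescaled")
    if detected_end is None:
        detected_end = curve.final
    end_exact, _ = end_percentage(native_embolized, detected_end, total_vessels)
    if start_at_native:
        lo = 100.0 * native_embolized / total_vessels
        percent = lo + curve.values / curve.final * (end_exact - lo)
    else:
        percent = curve.values / curve.final * end_exact
    return percent, end_exact


# ---------------------------------------------------------------------------
# stress–strain mapping
# ---------------------------------------------------------------------------

@dataclass
class StressStrainModel:
    """Three-segment continuous linear map from xylem strain to ψ_x (MPa).

    ψ(s) = intercept + m1·min(s, b1) + m2·clip(s − b1, 0, b2 − b1)
                     + m3·max(s − b2, 0)
    with slopes (m1, m2, m3) in MPa per strain unit and breakpoints b1 < b2.
    """

    breakpoints: tuple[float, float]
    intercept: float
    slopes: tuple[float, float, float]
    strain_range: tuple[float, float] | None = None
    segment_r2: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        b1, b2 = self.breakpoints
        if not b1 < b2:
            raise ValueError("breakpoints must satisfy b1 < b2")

    def psi(self, strain) -> np.ndarray:
        s = np.asarray(strain, dtype=float)
        b1, b2 = self.breakpoints
        m1, m2, m3 = self.slopes
        out = (
            self.intercept
            + m1 * np.minimum(s, b1)
            + m2 * np.clip(s - b1, 0.0, b2 - b1)
            + m3 * np.maximum(s - b2, 0.0)
        )
        return out if out.ndim else float(out)


def fit_stress_strain(
    strain,
    psi,
    n_breakpoints: int = 2,
    n_grid: int = 25,
) -> StressStrainModel:
    """Fit the segmented-linear stress–strain relation by grid search.

    Candidate breakpoint pairs are drawn from the observed strain quantiles
    (``n_grid`` levels); for each pair a continuous piecewise-linear model is
    fitted by least squares and the pair minimizing the residual sum of
    squares wins.  Candidates leaving fewer than two points in any segment
    are skipped.  Per-segment R² values are reported on the winning fit.
    """
    if n_breakpoints != 2:
        raise NotImplementedError("only the two-breakpoint (three-segment) model is supported")
    s = np.asarray(strain, dtype=float)
    y = np.asarray(psi, dtype=float)
    if s.size < 6:
        raise ValueError("need at least 6 points to fit a three-segment model")

    grid = np.unique(np.quantile(s, np.linspace(0.05, 0.95, n_grid)))
    best = None
    for i in range(len(grid)):
        for j in range(i + 1, len(grid)):
            b1, b2 = grid[i], grid[j]
            seg = np.digitize(s, [b1, b2])
            if min(np.sum(seg == 0), np.sum(seg == 1), np.sum(seg == 2)) < 2:
                continue
            X = np.column_stack(
                [np.ones_like(s), s, np.maximum(s - b1, 0.0), np.maximum(s - b2, 0.0)]
            )
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ coef) ** 2))
            if best is None or sse < best[0]:
                best = (sse, b1, b2, coef)
    if best is None:
        raise ValueError("no valid breakpoint candidate (too few points per segment)")

    _, b1, b2, coef = best
    c0, m1, dm2, dm3 = coef
    slopes = (float(m1), float(m1 + dm2), float(m1 + dm2 + dm3))
    model = StressStrainModel(
        breakpoints=(float(b1), float(b2)),
        intercept=float(c0),
        slopes=slopes,
        strain_range=(float(s.min()), float(s.max())),
    )
    fitted = model.psi(s)
    seg = np.digitize(s, [b1, b2])
    r2 = []
    for k in range(3):
        yk, fk = y[seg == k], fitted[seg == k]
        sst = float(np.sum((yk - yk.mean()) ** 2))
        r2.append(1.0 - float(np.sum((yk - fk) ** 2)) / sst if sst > 0 else 1.0)
    model.segment_r2 = tuple(r2)
    return model


def map_time_to_psi(model: StressStrainModel, strain_trace) -> np.ndarray:
    """Evaluate ψ_x along a strain trace (array of strain samples).

    Strain outside the fitted range is mapped by linear extrapolation of the
    adjacent segment, with a warning.
    """
    s = np.asarray(strain_trace, dtype=float)
    if model.strain_range is not None:
        lo, hi = model.strain_range
        if np.any(s < lo - 1e-12) or np.any(s > hi + 1e-12):
            warnings.warn("strain outside fitted range: extrapolating linearly", stacklevel=2)
    return model.psi(s)


# ---------------------------------------------------------------------------
# vulnerability values and curve comparison
# ---------------------------------------------------------------------------

@dataclass
class VulnerabilityValues:
    """ψ_x (MPa) at fixed percentage-embolism levels."""

    v12: float | None = None
    v50: float | None = None
    v88: float | None = None
    v100: float | None = None
    levels: dict = field(default_factory=dict)

    def __getitem__(self, level: float):
        return self.levels.get(level)


def vulnerability_values(
    vc: VulnerabilityCurve,
    levels=(12.0, 50.0, 88.0, 100.0),
    spline_lam: float | None = None,
) -> VulnerabilityValues:
    """ψ_x at which the curve crosses each percentage level.

    The percentage series is made monotone (isotonic correction along
    decreasing ψ), a smoothing spline of percent vs ψ is fitted (stiffness by
    generalized cross-validation unless ``spline_lam`` is given), and each
    crossing is located by bisection on the fitted curve.  A level above the
    curve's ceiling is undefined (``None``) — e.g. a µCT curve capped at 91%
    has no 100% value.
    """
    order = np.argsort(vc.psi)  # ascending psi (most negative first)
    psi = vc.psi[order]
    pct = vc.percent[order]
    # isotonic along time = non-increasing along ascending psi
    pct = np.minimum.accumulate(pct)

    psi_u, inv = np.unique(psi, return_inverse=True)
    pct_u = np.bincount(inv, weights=pct) / np.bincount(inv)
    if len(psi_u) >= 5:
        spline = make_smoothing_spline(psi_u, pct_u, lam=spline_lam)
    else:
        spline = None

    grid = np.linspace(psi_u[0], psi_u[-1], 4096)
    if spline is not None:
        fgrid = np.asarray(spline(grid))
        # enforce non-increasing along ascending psi (non-decreasing in time)
        fgrid = np.maximum.accumulate(np.clip(fgrid, 0.0, None)[::-1])[::-1]
    else:
        fgrid = np.interp(grid, psi_u, pct_u)

    out = VulnerabilityValues()
    for level in levels:
        value = None
        if level <= vc.end_percent + 1e-9:
            # fgrid is non-increasing along ascending psi: the crossing sits at
            # the boundary of the prefix where fgrid >= level
            above = fgrid >= level - 1e-12
            if above.all():
                value = float(grid[-1])
            elif above.any():
                lo_idx = int(np.max(np.flatnonzero(above)))
                a, b = grid[lo_idx], grid[lo_idx + 1]
                fa, fb = fgrid[lo_idx], fgrid[lo_idx + 1]
                if spline is not None:
                    try:
                        value = float(brentq(lambda p: float(spline(p)) - level, a, b))
                    except ValueError:  # spline locally non-monotone at the bracket
                        value = float(a + (b - a) * (fa - level) / (fa - fb)) if fa != fb else float(a)
                else:
                    value = float(a + (b - a) * (fa - level) / (fa - fb)) if fa != fb else float(a)
        out.levels[level] = value
    out.v12 = out.levels.get(12.0)
    out.v50 = out.levels.get(50.0)
    out.v88 = out.levels.get(88.0)
    out.v100 = out.levels.get(100.0)
    return out


def relative_difference_percent(value: float, reference: float) -> tuple[float, int]:
    """Relative difference 100·|value − reference|/|reference|, exact and reported.

    The reported figure is rounded to the nearest integer percent, e.g. v50
    values of −2.30 vs −2.34 MPa differ by 1.7 → reported 2.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    exact = 100.0 * abs(value - reference) / abs(reference)
    return exact, int(round(exact))


def compare_curves(
    vc_a: VulnerabilityCurve,
    vc_ref: VulnerabilityCurve,
    n_grid: int = 200,
) -> dict:
    """Absolute difference in percentage embolism against a reference curve.

    Both curves are interpolated onto a common ψ grid spanning their overlap;
    the summary reports the mean and maximum absolute difference and the
    relative difference of the 50% points.
    """
    lo = max(vc_a.psi.min(), vc_ref.psi.min())
    hi = min(vc_a.psi.max(), vc_ref.psi.max())
    if not lo < hi:
        raise ValueError("vulnerability curves have non-overlapping psi ranges")
    grid = np.linspace(lo, hi, n_grid)

    def _interp(vc):
        order = np.argsort(vc.psi)
        return np.interp(grid, vc.psi[order], vc.percent[order])

    diff = np.abs(_interp(vc_a) - _interp(vc_ref))
    va = vulnerability_values(vc_a, levels=(50.0,))
    vr = vulnerability_values(vc_ref, levels=(50.0,))
    summary = {
        "psi_grid": grid,
        "abs_difference": diff,
        "mean_abs_difference": float(diff.mean()),
        "max_abs_difference": float(diff.max()),
    }
    if va.v50 is not None and vr.v50 is not None:
        exact, reported = relative_difference_percent(va.v50, vr.v50)
        summary["v50_a"] = va.v50
        summary["v50_ref"] = vr.v50
        summary["v50_relative_difference_percent"] = exact
        summary["v50_relative_difference_reported"] = reported
    return summary
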