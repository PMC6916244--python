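"""Synthetic dehydration experiments with known ground truth.

Generates the full record of a combined acoustic-emission / µCT drought
experiment on a small tree stem: an AE hit table (18 waveform parameters per
hit), a scan schedule of 4-min rotation windows interleaved with 6-min (day)
or 30-min (night) breaks, per-window embolism counts, a dendrometer strain
trace with point measurements of xylem water potential, and optionally µCT
slice stacks with planted grey→black vessel transitions.

The generative model mirrors the assumptions of the downstream classifier:
embolism and background hits draw their six discriminative waveform
parameters from two multivariate normals sharing a covariance; embolism
arrival times follow an inhomogeneous Poisson process whose intensity is the
derivative of a logistic vulnerability curve in ψ_x; background AE intensity
is a constant floor plus a component tracking the same dehydration course
(fibers, parenchyma and bark dry on the same schedule as the vessels, which
is why unfiltered AE curves resemble µCT curves in real experiments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ingest import FEATURE_COLUMNS, PARAMETER_COLUMNS, TIME_COLUMN, LabeledWindow
from .vc import StressStrainModel

__all__ = [
    "SimulationConfig",
    "SyntheticExperiment",
    "ImageSeries",
    "simulate_experiment",
    "simulate_image_series",
    "build_schedule",
    "write_experiment",
    "write_image_series",
    "scan_run_minutes",
    "DEFAULT_MU0",
    "DEFAULT_MU1",
    "DEFAULT_SIGMA",
]


def scan_run_minutes(n_projections: int = 7200, exposure_ms: float = 200.0) -> float:
    """Duration of one full scan run: projections × exposure time, in minutes.

    The default acquisition takes 7200 projections at 200 ms over six
    consecutive rotations → 24 min per run (4 min per rotation).
    """
    return n_projections * exposure_ms / 1000.0 / 60.0


# class means for (AMP dB, COUN –, DURATION µs, SIGSTRNGTH nVs, ABSENERGY aJ, FREQPP2 %).
# spreads keep the physically non-negative parameters (AMP, DURATION, FREQPP2)
# essentially free of boundary clipping, so the two-normal model is faithful
DEFAULT_MU0 = np.array([35.0, 8.0, 250.0, 2.0, 5.0, 25.0])
DEFAULT_MU1 = np.array([55.0, 40.0, 700.0, 30.0, 150.0, 45.0])

_FEATURE_SD = np.array([6.0, 12.0, 100.0, 11.0, 55.0, 10.0])
# shape/energy parameters co-vary strongly; the 100–200 kHz partial power is
# mildly anti-correlated with amplitude and counts
_FEATURE_CORR = np.array(
    [
        [1.0, 0.6, 0.6, 0.6, 0.6, -0.3],
        [0.6, 1.0, 0.6, 0.6, 0.6, -0.3],
        [0.6, 0.6, 1.0, 0.6, 0.6, 0.0],
        [0.6, 0.6, 0.6, 1.0, 0.6, 0.0],
        [0.6, 0.6, 0.6, 0.6, 1.0, 0.0],
        [-0.3, -0.3, 0.0, 0.0, 0.0, 1.0],
    ]
)
DEFAULT_SIGMA = _FEATURE_CORR * np.outer(_FEATURE_SD, _FEATURE_SD)

# log-normal (median, sigma_log) models for the 12 remaining waveform
# parameters; nuisance columns so the full 18-column schema is exercised
_NUISANCE_LOGNORMAL = {
    "RISE": (20.0, 0.8),
    "ENER": (5.0, 1.0),
    "AFRQ": (150.0, 0.4),
    "RMS": (1.0, 0.7),
    "ASL": (22.0, 0.3),
    "RFRQ": (120.0, 0.4),
    "IFRQ": (180.0, 0.5),
    "FRQC": (200.0, 0.3),
    "PFRQ": (150.0, 0.5),
}


def _default_strain_model() -> StressStrainModel:
    # elastic shrinkage, plateau, then steep collapse once most vessels empty
    return StressStrainModel(
        breakpoints=(0.5, 1.2),
        intercept=-0.2,
        slopes=(-2.0, -1.5, -5.0),
        strain_range=(0.0, 2.0),
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dehydration experiment.

    Defaults reproduce the scale of a three-day bench campaign: 1100 vessels
    of which 541 natively embolized, an expectation of 457 new embolisms over
    the run, ~25,000 background hits, 6 × 4-min rotations per scan run with
    6-min day / 30-min night breaks.
    """

    seed: int = 0
    total_duration_h: float = 72.0
    start_hour: float = 8.0                 # clock hour at experiment start
    day_hours: tuple[float, float] = (7.0, 22.0)
    n_rotations: int = 6
    rotation_minutes: float = 4.0
    day_break_minutes: float = 6.0
    night_break_minutes: float = 30.0

    n_vessels_total: int = 1100
    n_native_embolized: int = 541
    expected_embolisms: float = 457.0
    psi50_mpa: float = -2.3                 # midpoint of the logistic embolism course
    psi_slope_mpa: float = 0.5              # logistic scale in MPa

    background_total: float = 25444.0       # expected non-embolism hits over the run
    background_floor_fraction: float = 0.2  # share arriving at a constant rate
    embolism_hazard: object = None          # optional rate override, hits/s at time t (s)
    background_rate: object = None          # optional rate override, hits/s at time t (s)

    mu0: np.ndarray = field(default_factory=lambda: DEFAULT_MU0.copy())
    mu1: np.ndarray = field(default_factory=lambda: DEFAULT_MU1.copy())
    sigma: np.ndarray = field(default_factory=lambda: DEFAULT_SIGMA.copy())
    contamination_fraction: float = 0.02
    contamination_scale: float = 3.0

    strain_model: StressStrainModel = field(default_factory=_default_strain_model)
    strain_max: float = 2.0
    strain_exponent: float = 1.2
    strain_sample_minutes: float = 1.0
    strain_noise: float = 0.0
    psi_every_minutes: float = 120.0        # spacing of pressure-chamber points
    psi_noise_mpa: float = 0.05

    # µCT image fixtures (arbitrary rendering constants, not field claims)
    image_size: int = 256
    image_n_slices: int = 60
    image_n_vessels: int = 150
    vessel_radius_px: tuple[float, float] = (2.0, 6.0)
    matrix_level: float = 90.0
    vessel_level: float = 140.0
    embolized_level: float = 30.0
    image_noise_sd: float = 0.0
    image_drift_px: float = 0.0

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu0.shape != (6,) or self.mu1.shape != (6,):
            raise ValueError("mu0 and mu1 must be 6-vectors")
        if self.sigma.shape != (6, 6) or not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be a symmetric 6x6 matrix")
        try:
            np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError:
            raise ValueError("sigma must be positive-definite") from None
        available = self.n_vessels_total - self.n_native_embolized
        if self.expected_embolisms > available:
            raise ValueError(
                f"expected embolisms {self.expected_embolisms} exceed the "
                f"{available} vessels still water-filled"
            )
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1)")

    # --- ground-truth trajectories -------------------------------------

    def strain_of_time(self, t_seconds) -> np.ndarray:
        """Monotone dendrometer shrinkage trajectory (µm mm⁻¹)."""
        T = self.total_duration_h * 3600.0
        frac = np.clip(np.asarray(t_seconds, dtype=float) / T, 0.0, 1.0)
        return self.strain_max * frac**self.strain_exponent

    def psi_of_time(self, t_seconds) -> np.ndarray:
        """Ground-truth ψ_x(t) (MPa) through the stress–strain model."""
        return self.strain_model.psi(self.strain_of_time(t_seconds))

    def embolism_cdf_shape(self, t_seconds) -> np.ndarray:
        """Unnormalized cumulative embolism course: logistic in ψ_x(t)."""
        psi = self.psi_of_time(t_seconds)
        return 1.0 / (1.0 + np.exp((psi - self.psi50_mpa) / self.psi_slope_mpa))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu0"] = self.mu0.tolist()
        d["mu1"] = self.mu1.tolist()
        d["sigma"] = self.sigma.tolist()
        d["strain_model"] = {
            "breakpoints": list(self.strain_model.breakpoints),
            "intercept": self.strain_model.intercept,
            "slopes": list(self.strain_model.slopes),
            "strain_range": list(self.strain_model.strain_range or ()),
        }
        d["embolism_hazard"] = None
        d["background_rate"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        sm = d.get("strain_model")
        if isinstance(sm, dict):
            d["strain_model"] = StressStrainModel(
                breakpoints=tuple(sm["breakpoints"]),
                intercept=sm["intercept"],
                slopes=tuple(sm["slopes"]),
                strain_range=tuple(sm["strain_range"]) or None,
            )
        for key in ("day_hours", "vessel_radius_px"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment with hidden per-hit truth."""

    config: SimulationConfig
    signals: pd.DataFrame              # TIME_S + 18 waveform parameters, time-sorted
    labels: np.ndarray                 # hidden truth: True = embolism hit
    windows: list                      # LabeledWindow with true per-window counts
    schedule: pd.DataFrame             # index, start_s, end_s, kind, embolism_count
    strain_trace: pd.DataFrame         # time_s, strain
    psi_points: pd.DataFrame           # time_s, psi_mpa

    @property
    def n_embolism(self) -> int:
        return int(self.labels.sum())


def build_schedule(config: SimulationConfig) -> pd.DataFrame:
    """Alternating scan-event and break windows covering the run.

    Each scan run is ``n_rotations`` consecutive rotation windows followed by
    one break whose length depends on the clock time (day vs night).  The
    last partial window is dropped so that every window is complete.
    """
    T = config.total_duration_h * 3600.0
    rows = []
    t = 0.0
    idx = 0
    while True:
        for _ in range(config.n_rotations):
            end = t + config.rotation_minutes * 60.0
            if end > T:
                return pd.DataFrame(rows)
            rows.append({"index": idx, "start_s": t, "end_s": end, "kind": "scan"})
            idx += 1
            t = end
        hour = (config.start_hour + t / 3600.0) % 24.0
        is_day = config.day_hours[0] <= hour < config.day_hours[1]
        brk = (config.day_break_minutes if is_day else config.night_break_minutes) * 60.0
        if t + brk > T:
            return pd.DataFrame(rows)
        rows.append({"index": idx, "start_s": t, "end_s": t + brk, "kind": "break"})
        idx += 1
        t += brk


def _sample_inhomogeneous(rng: np.random.Generator, rate_of_t, t_end: float) -> np.ndarray:
    """Inhomogeneous Poisson arrival times on [0, t_end) by thinning.

    ``rate_of_t`` maps time (s) to intensity (hits/s); the bound for thinning
    is taken from a 1-min evaluation grid.
    """
    grid = np.linspace(0.0, t_end, max(2, int(t_end / 60.0) + 1))
    rates = np.asarray(rate_of_t(grid), dtype=float)
    if np.any(rates < 0):
        raise ValueError("intensity function must be non-negative")
    rmax = float(rates.max())
    if rmax == 0.0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, n_cand))
    keep = rng.uniform(0.0, rmax, n_cand) < np.asarray(rate_of_t(cand), dtype=float)
    return cand[keep]


def _interp_rate(tgrid: np.ndarray, values: np.ndarray):
    return lambda t: np.interp(np.asarray(t, dtype=float), tgrid, values)


def _default_rates(config: SimulationConfig, t_end: float):
    """Built-in embolism and background intensities (hits/s) on [0, t_end)."""
    tgrid = np.linspace(0.0, t_end, max(2, int(t_end / 60.0) + 1))
    shape = config.embolism_cdf_shape(tgrid)
    span = shape[-1] - shape[0]
    if span <= 0:
        density = np.zeros_like(tgrid)
    else:
        cum = (shape - shape[0]) / span
        density = np.gradient(cum, tgrid)
        density = np.clip(density, 0.0, None)
        density /= np.trapezoid(density, tgrid)
    emb = config.expected_embolisms * density
    floor = config.background_total * config.background_floor_fraction / t_end
    bg = floor + config.background_total * (1.0 - config.background_floor_fraction) * density
    return _interp_rate(tgrid, emb), _interp_rate(tgrid, bg)


def _draw_features(rng: np.random.Generator, mu, sigma, n, contamination=0.0, scale=3.0):
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, 6))
    if contamination > 0 and n > 0:
        heavy = rng.random(n) < contamination
        z[heavy] *= scale
    return mu + z @ chol.T


def _nuisance_table(rng: np.random.Generator, n: int) -> dict:
    cols = {}
    for name, (median, sd_log) in _NUISANCE_LOGNORMAL.items():
        cols[name] = median * np.exp(rng.standard_normal(n) * sd_log)
    return cols


def _assemble_signals(rng: np.random.Generator, config, times, labels) -> pd.DataFrame:
    """Build the full 18-parameter hit table from feature draws.

    FREQPP2 comes from the class model (clipped into [0, 100]); the remaining
    partial powers split the residual spectral mass on a Dirichlet simplex so
    that FREQPP1–4 sum to exactly 100% per hit.
    """
    n = len(times)
    feats = np.empty((n, 6))
    emb = labels
    feats[emb] = _draw_features(rng, config.mu1, config.sigma, int(emb.sum()))
    feats[~emb] = _draw_features(
        rng,
        config.mu0,
        config.sigma,
        int((~emb).sum()),
        contamination=config.contamination_fraction,
        scale=config.contamination_scale,
    )
    table = {TIME_COLUMN: times}
    for j, name in enumerate(FEATURE_COLUMNS):
        table[name] = feats[:, j]
    table["AMP"] = np.clip(table["AMP"], 0.0, None)
    table["DURATION"] = np.clip(table["DURATION"], 0.0, None)
    table["FREQPP2"] = np.clip(table["FREQPP2"], 0.0, 100.0)
    rest = 100.0 - table["FREQPP2"]
    simplex = rng.dirichlet([3.0, 2.0, 1.0], size=n) if n else np.empty((0, 3))
    table["FREQPP1"] = rest * simplex[:, 0] if n else np.empty(0)
    table["FREQPP3"] = rest * simplex[:, 1] if n else np.empty(0)
    table["FREQPP4"] = rest * simplex[:, 2] if n else np.empty(0)
    table.update(_nuisance_table(rng, n))
    df = pd.DataFrame(table)
    return df[[TIME_COLUMN] + list(PARAMETER_COLUMNS)]


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Generate one synthetic experiment; bitwise reproducible for a seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_emb, rng_bg, rng_feat, rng_meas = [np.random.default_rng(s) for s in ss.spawn(4)]

    schedule = build_schedule(config)
    if schedule.empty:
        raise ValueError("schedule is empty: total_duration_h too short for one rotation")
    t_end = float(schedule["end_s"].iloc[-1])

    emb_rate, bg_rate = _default_rates(config, t_end)
    if config.embolism_hazard is not None:
        emb_rate = config.embolism_hazard
    if config.background_rate is not None:
        bg_rate = config.background_rate

    t_emb = _sample_inhomogeneous(rng_emb, emb_rate, t_end)
    available = config.n_vessels_total - config.n_native_embolized
    if len(t_emb) > available:  # pragma: no cover - ~5 sigma event at defaults
        t_emb = t_emb[rng_emb.permutation(len(t_emb))[:available]]
        t_emb.sort()
    t_bg = _sample_inhomogeneous(rng_bg, bg_rate, t_end)

    times = np.concatenate([t_emb, t_bg])
    labels = np.concatenate([np.ones(len(t_emb), bool), np.zeros(len(t_bg), bool)])
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]

    signals = _assemble_signals(rng_feat, config, times, labels)

    # true per-window counts and memberships (half-open [start, end))
    starts = schedule["start_s"].to_numpy()
    ends = schedule["end_s"].to_numpy()
    idx = np.searchsorted(starts, times, side="right") - 1
    inside = (idx >= 0) & (times < ends[np.clip(idx, 0, None)])
    windows = []
    for w in range(len(schedule)):
        members = np.flatnonzero(inside & (idx == w))
        windows.append(
            LabeledWindow(
                index=int(schedule["index"].iloc[w]),
                start=float(starts[w]),
                end=float(ends[w]),
                kind=str(schedule["kind"].iloc[w]),
                embolism_count=int(labels[members].sum()),
                signal_indices=members,
            )
        )
    schedule = schedule.assign(embolism_count=[w.embolism_count for w in windows])

    # dendrometer trace and pressure-chamber points
    t_strain = np.arange(0.0, t_end + 1e-9, config.strain_sample_minutes * 60.0)
    strain = config.strain_of_time(t_strain)
    if config.strain_noise > 0:
        strain = strain + rng_meas.normal(0.0, config.strain_noise, len(strain))
    strain_trace = pd.DataFrame({"time_s": t_strain, "strain": strain})

    day_breaks = schedule[(schedule["kind"] == "break")]
    candidates = []
    for _, row in day_breaks.iterrows():
        hour = (config.start_hour + row["start_s"] / 3600.0) % 24.0
        if config.day_hours[0] <= hour < config.day_hours[1]:
            candidates.append(0.5 * (row["start_s"] + row["end_s"]))
    psi_times, last = [], -np.inf
    for t in candidates:
        if t - last >= config.psi_every_minutes * 60.0:
            psi_times.append(t)
            last = t
    psi_times = np.asarray(psi_times)
    psi_vals = config.psi_of_time(psi_times)
    if config.psi_noise_mpa > 0 and len(psi_times):
        psi_vals = psi_vals + rng_meas.normal(0.0, config.psi_noise_mpa, len(psi_times))
    psi_points = pd.DataFrame({"time_s": psi_times, "psi_mpa": psi_vals})

    return SyntheticExperiment(
        config=config,
        signals=signals,
        labels=labels,
        windows=windows,
        schedule=schedule,
        strain_trace=strain_trace,
        psi_points=psi_points,
    )


# ---------------------------------------------------------------------------
# µCT image fixtures
# ---------------------------------------------------------------------------

@dataclass
class ImageSeries:
    """Slice stacks bracketing the windows, with planted ground truth.

    ``stacks[i]`` images the state before window ``i``; ``stacks[i+1]`` the
    state after it, so window ``i``'s transitions happen between consecutive
    stacks.  ``planted`` lists the (x, y) centers (row, column = y, x) of the
    vessels that emptied in each window, in the undrifted base frame.
    """

    stacks: list
    planted: pd.DataFrame  # window_pos, x, y, radius
    vessel_map: pd.DataFrame  # x, y, radius, initially_embolized


def _pack_vessels(rng, config) -> pd.DataFrame:
    """Disc-packed cross-section: non-overlapping vessel discs inside the stem."""
    size = config.image_size
    cx = cy = size / 2.0
    section_r = 0.42 * size
    rmin, rmax = config.vessel_radius_px
    xs, ys, rs = [], [], []
    attempts = 0
    while len(xs) < config.image_n_vessels and attempts < 40000:
        attempts += 1
        r = rng.uniform(rmin, rmax)
        rho = (section_r - r - 2.0) * np.sqrt(rng.random())
        theta = rng.uniform(0, 2 * np.pi)
        x = cx + rho * np.cos(theta)
        y = cy + rho * np.sin(theta)
        if xs:
            d = np.hypot(np.array(xs) - x, np.array(ys) - y)
            if np.any(d < np.array(rs) + r + 3.0):
                continue
        xs.append(x)
        ys.append(y)
        rs.append(r)
    if len(xs) < config.image_n_vessels:
        raise ValueError(
            f"could not pack {config.image_n_vessels} vessels into a {size}px section; "
            "reduce image_n_vessels or vessel radii"
        )
    native_frac = config.n_native_embolized / config.n_vessels_total
    native = rng.random(len(xs)) < native_frac
    return pd.DataFrame({"x": xs, "y": ys, "radius": rs, "initially_embolized": native})


def _render_stack(config, vessels, embolized, rng, drift):
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = size / 2.0
    base = np.zeros((size, size), dtype=float)
    base[(xx - cx) ** 2 + (yy - cy) ** 2 <= (0.45 * size) ** 2] = config.matrix_level
    for (x, y, r), emb in zip(vessels[["x", "y", "radius"]].to_numpy(), embolized):
        level = config.embolized_level if emb else config.vessel_level
        base[(xx - x) ** 2 + (yy - y) ** 2 <= r**2] = level
    if drift is not None and (drift[0] != 0 or drift[1] != 0):
        from scipy.ndimage import shift as nd_shift

        base = nd_shift(base, drift, order=1, mode="nearest")
    stack = np.repeat(base[None, :, :], config.image_n_slices, axis=0)
    if config.image_noise_sd > 0:
        stack = stack + rng.normal(0.0, config.image_noise_sd, stack.shape)
    return np.clip(stack, 0.0, 255.0).astype(np.float32)


def simulate_image_series(
    config: SimulationConfig,
    windows: list,
    seed: int | None = None,
) -> ImageSeries:
    """Render slice stacks in which each window's count of vessels turns black.

    Raises if the windows request more transitions than there are still-grey
    vessels in the rendered section.
    """
    starts = [w.start for w in windows]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("windows must be chronologically ordered")
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    vessels = _pack_vessels(rng, config)
    state = vessels["initially_embolized"].to_numpy().copy()
    needed = int(sum(w.embolism_count for w in windows))
    if needed > int((~state).sum()):
        raise ValueError(
            f"windows request {needed} transitions but only {(~state).sum()} grey vessels remain"
        )

    stacks = [_render_stack(config, vessels, state, rng, drift=(0.0, 0.0))]
    planted_rows = []
    drift = np.zeros(2)
    for pos, w in enumerate(windows):
        grey = np.flatnonzero(~state)
        chosen = rng.choice(grey, size=w.embolism_count, replace=False)
        state[chosen] = True
        for c in chosen:
            planted_rows.append(
                {
                    "window_pos": pos,
                    "x": vessels["x"].iloc[c],
                    "y": vessels["y"].iloc[c],
                    "radius": vessels["radius"].iloc[c],
                }
            )
        if config.image_drift_px > 0:
            drift = drift + rng.uniform(-config.image_drift_px, config.image_drift_px, 2)
        stacks.append(_render_stack(config, vessels, state, rng, drift=tuple(drift)))
    planted = pd.DataFrame(planted_rows, columns=["window_pos", "x", "y", "radius"])
    return ImageSeries(stacks=stacks, planted=planted, vessel_map=vessels)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_experiment(exp: SyntheticExperiment, outdir) -> dict:
    """Write the experiment as delimited text + YAML config; returns paths."""
    from pathlib import Path

    from .ingest import write_ae_table, write_schedule

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ae_table": out / "ae_table.tsv",
        "schedule": out / "schedule.tsv",
        "strain": out / "strain_trace.tsv",
        "psi_points": out / "psi_points.tsv",
        "config": out / "config.yaml",
        "truth_labels": out / "truth_labels.tsv",
    }
    write_ae_table(exp.signals, paths["ae_table"])
    write_schedule(exp.windows, paths["schedule"])
    exp.strain_trace.to_csv(paths["strain"], sep="\t", index=False)
    exp.psi_points.to_csv(paths["psi_points"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(exp.config.to_dict(), fh, sort_keys=True)
    pd.DataFrame({"is_embolism": exp.labels.astype(int)}).to_csv(
        paths["truth_labels"], sep="\t", index=False
    )
    return {k: str(v) for k, v in paths.items()}


def write_image_series(series: ImageSeries, outdir) -> list:
    """Write each stack as numbered TIFF slices under stack_###/ directories."""
    from pathlib import Path

    import tifffile

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stack_dirs = []
    for i, stack in enumerate(series.stacks):
        d = out / f"stack_{i:03d}"
        d.mkdir(exist_ok=True)
        for j, sl in enumerate(stack):
            tifffile.imwrite(d / f"slice_{j:04d}.tif", sl.astype(np.float32))
        stack_dirs.append(str(d))
    series.planted.to_csv(out / "planted_transitions.tsv", sep="\t", index=False)
    return stack_dirs
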