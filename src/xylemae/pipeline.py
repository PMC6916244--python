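"""End-to-end orchestration: simulate → ingest → detect → explore → LDA → VC.

Stage outputs are files, so each stage can be re-run independently; every
threshold and convention in force is recorded in the report.  ``run_full``
mirrors a complete experiment analysis: noise filtering, windowing against
the µCT schedule, exploratory screening, count-weighted LDA with
leave-one-window-out validation, and the three vulnerability curves
(unfiltered AE, LDA-filtered AE, µCT) with their 12/50/88/100% values and
pairwise comparisons against the µCT reference.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import explore, ingest, lda, uct, vc
from .simulate import SimulationConfig, simulate_experiment, write_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a full analysis run; every numeric default in the report
    traces back to one of these keys."""

    # inputs: either a simulation config or paths to on-disk tables
    simulation: SimulationConfig | None = None
    ae_table: str | None = None
    schedule: str | None = None
    strain_trace: str | None = None
    psi_points: str | None = None
    image_dir: str | None = None

    noise_threshold_db: float = ingest.NOISE_THRESHOLD_DB
    maxima_threshold: float = uct.MAXIMA_THRESHOLD
    min_separation_px: int = uct.MIN_SEPARATION_PX
    bin_minutes: float = 10.0
    d1_window_minutes: float = 15.0
    d3_window_minutes: float = 48 * 60.0
    n_vessels_total: int = 1100
    n_native_embolized: int = 541
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


#: The reading adopted for every convention the analysis leaves open.
CONVENTIONS = {
    "noise_filter": "retain hits with AMP strictly above the threshold",
    "window_assignment": "half-open [start, end): boundary hits join the window they start",
    "roc_counting": "true positives capped at the window's µCT count",
    "rescaling": "native embolisms raise only the percentage ceiling; curves start at 0",
    "cumulation": "bin value is the exact time average of the running sum in the bin",
    "derivatives": "iterated centered windowed least-squares slopes",
    "covariance_weighting": "window-size-weighted average of within-window covariances",
    "prior": "global count ratio sum(n1)/sum(m)",
}


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic experiment and write its fixture files."""
    if config.simulation is None:
        raise ValueError("run_simulate requires a simulation config")
    exp = simulate_experiment(config.simulation)
    out = Path(config.outdir)
    paths = write_experiment(exp, out)
    logger.info("wrote synthetic experiment to %s", out)
    return paths


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        exp = simulate_experiment(config.simulation)
        return exp.signals, exp.schedule, exp.strain_trace, exp.psi_points
    if not (config.ae_table and config.schedule):
        raise ValueError("either a simulation config or ae_table+schedule paths are required")
    signals = ingest.read_ae_table(config.ae_table)
    schedule = ingest.read_schedule(config.schedule)
    strain = pd.read_csv(config.strain_trace, sep="\t") if config.strain_trace else None
    psi = pd.read_csv(config.psi_points, sep="\t") if config.psi_points else None
    return signals, schedule, strain, psi


def detect_counts(config: PipelineConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Run the µCT detector over stack directories → per-window counts."""
    if not config.image_dir:
        raise ValueError("detect requires image_dir")
    stack_dirs = sorted(p for p in Path(config.image_dir).iterdir() if p.is_dir())
    stacks = [uct.read_stack_dir(d, window_index=i) for i, d in enumerate(stack_dirs)]
    counts, events = uct.count_series(
        stacks,
        maxima_threshold=config.maxima_threshold,
        min_separation=config.min_separation_px,
    )
    return counts, uct.events_table(events)


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the report dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"conventions": dict(CONVENTIONS), "config": config.to_dict()}

    signals, schedule, strain_trace, psi_points = _load_inputs(config)

    # --- ingest ---------------------------------------------------------
    retained = ingest.filter_noise(signals, config.noise_threshold_db)
    report["n_signals_raw"] = int(len(signals))
    report["n_signals_retained"] = int(len(retained))

    counts = None
    if config.image_dir:
        counts, events = detect_counts(config)
        events.to_csv(out / "uct_events.tsv", sep="\t", index=False)
        if len(counts) != len(schedule):
            raise ValueError(
                f"detected counts for {len(counts)} windows but schedule has {len(schedule)}"
            )
    windows, orphans = ingest.link_windows(retained, schedule, per_window_counts=counts)
    ingest.write_schedule(windows, out / "windows.tsv")
    report["n_windows"] = len(windows)
    report["n_orphans"] = int(len(orphans))
    observed_total = float(sum(w.embolism_count for w in windows))
    report["uct_observed_total"] = observed_total

    # --- exploratory screening ------------------------------------------
    corr = explore.correlation_matrix(retained)
    corr.to_csv(out / "correlation_matrix.tsv", sep="\t")
    pca = explore.pca_summary(
        retained[list(ingest.PARAMETER_COLUMNS)].to_numpy(), columns=list(ingest.PARAMETER_COLUMNS)
    )
    pd.DataFrame(
        {"component": np.arange(1, len(pca.explained_variance_ratio) + 1),
         "explained_variance_fraction": pca.explained_variance_ratio}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    report["pca_top2_variance_percent"] = [
        float(100 * v) for v in pca.explained_variance_ratio[:2]
    ]

    roc_aucs = {}
    if observed_total > 0:
        for param in ingest.FEATURE_COLUMNS:
            curve = explore.roc_parameter(retained, windows, param)
            curve.to_frame().to_csv(out / f"roc_{param}.tsv", sep="\t", index=False)
            roc_aucs[param] = curve.auc
    report["roc_auc_parameters"] = roc_aucs

    # --- count-weighted LDA ----------------------------------------------
    features = ingest.extract_features(retained)
    lda_ok = True
    try:
        model = lda.fit_weighted_lda(windows, features)
    except ValueError as exc:
        lda_ok = False
        report["lda_error"] = str(exc)
        logger.warning("LDA stage skipped: %s", exc)
    if lda_ok:
        with open(out / "lda_model.yaml", "w") as fh:
            yaml.safe_dump(model.to_dict(), fh, sort_keys=True)
        posteriors = lda.posterior(model, features)
        loo = lda.loo_crossvalidate(windows, features)
        loo.table.to_csv(out / "loo_counts.tsv", sep="\t", index=False)
        report["lda_predicted_total"] = loo.predicted_total
        report["lda_max_posterior"] = float(posteriors.max()) if len(posteriors) else None
        curve = lda.roc_lda(windows, posteriors)
        curve.to_frame().to_csv(out / "roc_LDA.tsv", sep="\t", index=False)
        roc_aucs["LDA"] = curve.auc

    # --- vulnerability curves --------------------------------------------
    span = (float(schedule["start_s"].iloc[0]), float(schedule["end_s"].iloc[-1]))
    times = retained[ingest.TIME_COLUMN].to_numpy()
    cum_ae = vc.cumulate(times, bin_minutes=config.bin_minutes, span=span)

    endpoint = None
    try:
        endpoint = vc.find_endpoint(
            cum_ae, config.d1_window_minutes, config.d3_window_minutes
        )
    except ValueError as exc:
        report["endpoint_note"] = f"derivative window exceeds series: {exc}"
    report["ae_endpoint_s"] = endpoint
    report["ae_endpoint_defined"] = endpoint is not None

    psi_of_time = None
    if strain_trace is not None and psi_points is not None and len(psi_points) >= 6:
        strain_at_psi = np.interp(
            psi_points["time_s"], strain_trace["time_s"], strain_trace["strain"]
        )
        ss_model = vc.fit_stress_strain(strain_at_psi, psi_points["psi_mpa"].to_numpy())
        report["stress_strain"] = {
            "breakpoints": list(ss_model.breakpoints),
            "slopes": list(ss_model.slopes),
            "segment_r2": list(ss_model.segment_r2),
        }

        def psi_of_time(t):
            import warnings as _warnings

            s = np.interp(t, strain_trace["time_s"], strain_trace["strain"])
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                out_psi = vc.map_time_to_psi(ss_model, s)
            for w in caught:  # log instead of spamming per-curve warnings
                logger.info("%s", w.message)
            return out_psi

    def build_curve(cumcurve, detected_end, name):
        percent, end_exact = vc.rescale_percentage(
            cumcurve,
            config.n_native_embolized,
            detected_end,
            config.n_vessels_total,
        )
        frame = pd.DataFrame({"time_s": cumcurve.bin_centers, "percent": percent})
        curve_obj = None
        if psi_of_time is not None:
            frame["psi_mpa"] = psi_of_time(cumcurve.bin_centers)
            curve_obj = vc.VulnerabilityCurve(
                psi=frame["psi_mpa"].to_numpy(), percent=percent, end_percent=end_exact
            )
        frame.to_csv(out / f"vc_{name}.tsv", sep="\t", index=False)
        report[f"end_percent_{name}"] = end_exact
        return curve_obj

    curves = {}
    # unfiltered AE: every retained hit weighted 1, rescaled over the full axis
    if cum_ae.final > 0:
        available = config.n_vessels_total - config.n_native_embolized
        curves["ae"] = build_curve(cum_ae, available, "ae")
    if observed_total > 0:
        cum_ct = vc.cumulate(
            np.array([w.end for w in windows]),
            weights=np.array([float(w.embolism_count) for w in windows]),
            bin_minutes=config.bin_minutes,
            span=span,
        )
        curves["ct"] = build_curve(cum_ct, observed_total, "ct")
    if lda_ok and len(retained):
        cum_lda = vc.cumulate(
            times, weights=posteriors, bin_minutes=config.bin_minutes, span=span
        )
        if cum_lda.final > 0:
            detected = min(
                loo.predicted_total, config.n_vessels_total - config.n_native_embolized
            )
            curves["lda"] = build_curve(cum_lda, detected, "lda")

    values_rows = []
    for name, curve_obj in curves.items():
        if curve_obj is None:
            continue
        vals = vc.vulnerability_values(curve_obj)
        values_rows.append(
            {"curve": name, "v12": vals.v12, "v50": vals.v50, "v88": vals.v88, "v100": vals.v100}
        )
        report[f"v50_{name}"] = vals.v50
    if values_rows:
        pd.DataFrame(values_rows).to_csv(out / "vulnerability_values.tsv", sep="\t", index=False)

    if curves.get("ct") is not None:
        for name in ("ae", "lda"):
            if curves.get(name) is not None:
                cmp = vc.compare_curves(curves[name], curves["ct"])
                pd.DataFrame(
                    {"psi_mpa": cmp["psi_grid"], "abs_difference": cmp["abs_difference"]}
                ).to_csv(out / f"comparison_{name}_vs_ct.tsv", sep="\t", index=False)
                report[f"comparison_{name}_vs_ct"] = {
                    k: cmp[k]
                    for k in (
                        "mean_abs_difference",
                        "max_abs_difference",
                        "v50_a",
                        "v50_ref",
                        "v50_relative_difference_percent",
                        "v50_relative_difference_reported",
                    )
                    if k in cmp
                }

    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=True)
    return report


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
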