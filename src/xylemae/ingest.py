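"""Reading AE hit tables, noise filtering, and windowing against the µCT timeline.

Acoustic-emission acquisition systems export one row per registered hit,
carrying a timestamp and a fixed set of waveform parameters (peak amplitude,
counts, duration, signal strength, absolute energy, partial spectral powers,
...).  This module reads such tables, applies the amplitude noise filter, and
partitions the retained hits into the labeled time windows defined by the
µCT scan schedule: each window knows how many new embolisms the scanner saw,
which is the weak supervision consumed by :mod:`xylemae.lda`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Time column: seconds since experiment start.
TIME_COLUMN = "TIME_S"

#: The 18 AE waveform parameters exported per hit, in canonical order.
#: Units: RISE µs; COUN –; ENER 1e-14 V²s; DURATION µs; AMP dB; AFRQ kHz;
#: RMS µV; ASL dB; RFRQ kHz; IFRQ kHz; SIGSTRNGTH 1e-9 Vs; ABSENERGY aJ;
#: FREQPP1–4 %; FRQC kHz; PFRQ kHz.
PARAMETER_COLUMNS = (
    "RISE",
    "COUN",
    "ENER",
    "DURATION",
    "AMP",
    "AFRQ",
    "RMS",
    "ASL",
    "RFRQ",
    "IFRQ",
    "SIGSTRNGTH",
    "ABSENERGY",
    "FREQPP1",
    "FREQPP2",
    "FREQPP3",
    "FREQPP4",
    "FRQC",
    "PFRQ",
)

#: The six parameters selected for embolism detection, in the fixed order
#: used throughout the classifier: amplitude (dB), counts (–), duration (µs),
#: signal strength (nVs), absolute energy (aJ), partial power 100–200 kHz (%).
FEATURE_COLUMNS = ("AMP", "COUN", "DURATION", "SIGSTRNGTH", "ABSENERGY", "FREQPP2")

#: Default acquisition noise floor: hits at or below this peak amplitude are
#: discarded ("above the noise level" read as strict >).
NOISE_THRESHOLD_DB = 28.0

#: 20–1000 kHz acquisition band-pass filter; hardware metadata only, recorded
#: for provenance, never applied as a computation.
ACQUISITION_BANDPASS_KHZ = (20.0, 1000.0)


class FormatError(ValueError):
    """A table does not conform to the AE hit-table schema."""


@dataclass
class LabeledWindow:
    """A time span (scan event or break) with its µCT embolism count.

    ``signal_indices`` are positional row indices into the signal table the
    window was built from.  The half-open convention [start, end) assigns a
    hit sitting exactly on a boundary to the window it starts.
    """

    index: int
    start: float
    end: float
    kind: str  # "scan" | "break"
    embolism_count: int = 0
    signal_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window {self.index}: start {self.start} must precede end {self.end}")
        if self.embolism_count < 0:
            raise ValueError(f"window {self.index}: negative embolism count")
        self.signal_indices = np.asarray(self.signal_indices, dtype=int)

    @property
    def size(self) -> int:
        return int(len(self.signal_indices))

    def duration(self) -> float:
        return self.end - self.start


def read_ae_table(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited AE hit table into a DataFrame.

    The file must have one header row naming TIME_S and the 18 waveform
    parameter columns.  Columns may appear in any order; extra columns are
    ignored with a warning.  Rows are returned in file order with the columns
    rearranged to canonical order (TIME_S first).
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    mandatory = (TIME_COLUMN,) + PARAMETER_COLUMNS
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"AE table {path} is missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        logger.warning("AE table %s: ignoring unknown column(s) %s", path, ", ".join(extra))
    df = df[list(mandatory)]
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        for col in bad:
            rows = np.flatnonzero(pd.to_numeric(df[col], errors="coerce").isna().to_numpy())
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"AE table {path}: non-numeric value in column {col} at line {rows[0] + 2}"
            )
    return df.astype(float).reset_index(drop=True)


def write_ae_table(df: pd.DataFrame, path, *, sep: str = "\t") -> None:
    """Write a hit table in the canonical delimited-text layout.

    Floats are written with 17 significant digits so a write/read round trip
    is bit-exact.
    """
    cols = [TIME_COLUMN] + [c for c in PARAMETER_COLUMNS]
    df[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_schedule(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a window schedule table (index, start_s, end_s, kind[, embolism_count])."""
    df = pd.read_csv(path, sep=sep)
    for col in ("start_s", "end_s", "kind"):
        if col not in df.columns:
            raise FormatError(f"schedule {path} is missing column {col}")
    return df


def write_schedule(windows: list[LabeledWindow], path, *, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "index": [w.index for w in windows],
            "start_s": [w.start for w in windows],
            "end_s": [w.end for w in windows],
            "kind": [w.kind for w in windows],
            "embolism_count": [w.embolism_count for w in windows],
        }
    ).to_csv(path, sep=sep, index=False)


def filter_noise(signals: pd.DataFrame, threshold_db: float = NOISE_THRESHOLD_DB) -> pd.DataFrame:
    """Retain hits strictly above the amplitude noise floor.

    Row order is preserved; the positional index is reset so that window
    assignment downstream refers to the filtered table.  Idempotent.
    """
    return signals[signals["AMP"].to_numpy() > threshold_db].reset_index(drop=True)


def link_windows(
    signals: pd.DataFrame,
    schedule: pd.DataFrame,
    per_window_counts=None,
) -> tuple[list[LabeledWindow], np.ndarray]:
    """Assign each hit to the schedule window containing its timestamp.

    ``schedule`` rows must be chronologically ordered and non-overlapping.
    ``per_window_counts`` overrides/provides the µCT embolism count per
    window; if omitted the schedule's own ``embolism_count`` column is used
    (zeros if absent).  Returns the labeled windows and the positional
    indices of orphan hits falling outside every window (schedule gaps, e.g.
    acquisition put on hold during leaf excision).
    """
    starts = schedule["start_s"].to_numpy(dtype=float)
    ends = schedule["end_s"].to_numpy(dtype=float)
    if np.any(starts[1:] < ends[:-1]) or np.any(starts >= ends):
        raise ValueError("schedule windows must be ordered and non-overlapping")
    if per_window_counts is None:
        if "embolism_count" in schedule.columns:
            counts = schedule["embolism_count"].to_numpy(dtype=int)
        else:
            counts = np.zeros(len(schedule), dtype=int)
    else:
        counts = np.asarray(per_window_counts, dtype=int)
        if len(counts) != len(schedule):
            raise ValueError(
                f"counts length {len(counts)} does not match schedule length {len(schedule)}"
            )

    t = signals[TIME_COLUMN].to_numpy(dtype=float)
    # half-open [start, end): a hit exactly on a boundary joins the window it starts
    idx = np.searchsorted(starts, t, side="right") - 1
    inside = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
    orphans = np.flatnonzero(~inside)

    kinds = schedule["kind"].astype(str).to_list() if "kind" in schedule.columns else ["scan"] * len(schedule)
    windows = []
    for w in range(len(schedule)):
        members = np.flatnonzero(inside & (idx == w))
        windows.append(
            LabeledWindow(
                index=int(schedule["index"].iloc[w]) if "index" in schedule.columns else w,
                start=float(starts[w]),
                end=float(ends[w]),
                kind=kinds[w],
                embolism_count=int(counts[w]),
                signal_indices=members,
            )
        )
    return windows, orphans


def extract_features(signals: pd.DataFrame) -> np.ndarray:
    """Return the (n, 6) feature matrix in the fixed column order.

    Order: AMP, COUN, DURATION, SIGSTRNGTH, ABSENERGY, FREQPP2.
    """
    x = signals[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite entries")
    return x
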