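"""Reading and writing of chronoamperogram matrices and analysis reports.

The canonical on-disk form of a recording is a plain-text numeric matrix,
one column per electrode, optionally preceded by a single header row of
channel labels.  Tab, comma and generic whitespace delimiters are
auto-detected.  All report files are plain CSV so that any downstream
software can re-read them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Chronoamperogram",
    "ChronoamperogramFormatError",
    "load_chronoamperogram",
    "write_chronoamperogram",
    "write_spike_report",
    "write_feet_report",
]


class ChronoamperogramFormatError(ValueError):
    """Raised for malformed recording files (ragged rows, bad cells, ...)."""


@dataclass
class Chronoamperogram:
    """A multi-channel constant-potential current recording.

    ``samples`` holds gain-corrected currents in pA, shape
    (n_samples, n_channels); all channels share one time base derived from
    ``sampling_rate``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i + 1}" for i in range(self.samples.shape[1])]
        if len(self.channel_ids) != self.samples.shape[1]:
            raise ValueError("channel_ids length must match number of columns")
        if self.samples.shape[1] < 1:
            raise ValueError("at least one channel is required")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain missing values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording length: number of points divided by the sampling rate."""
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[:, self.channel_ids.index(channel_id)]

    def select(self, channel_ids: list[str]) -> "Chronoamperogram":
        """Keep a subset of channels, preserving their original order."""
        keep = [c for c in self.channel_ids if c in set(channel_ids)]
        missing = set(channel_ids) - set(self.channel_ids)
        if missing:
            raise KeyError(f"unknown channels: {sorted(missing)}")
        idx = [self.channel_ids.index(c) for c in keep]
        return Chronoamperogram(self.samples[:, idx], self.sampling_rate, keep)


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return r"\s+"


def _is_numeric_row(line: str, sep: str) -> bool:
    if sep == r"\s+":
        tokens = line.split()
    else:
        tokens = [t.strip() for t in line.split(sep)]
    if not tokens:
        return False
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def load_chronoamperogram(path, config, *, transpose: bool = False) -> Chronoamperogram:
    """Load a plain-text recording matrix and apply the front-end gain.

    Parameters
    ----------
    path : path-like
        Whitespace/tab/comma-delimited numeric text, one column per
        electrode, optional single header row of channel labels.
    config : AnalysisConfig
        Supplies ``sampling_rate``, ``gain`` and ``selected_channels``.
    transpose : bool
        Set for row-per-channel files.

    Returns
    -------
    Chronoamperogram
        Samples divided by ``config.gain`` (recorded values -> pA); only
        the selected channels are retained.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ChronoamperogramFormatError(f"{path}: empty input file")
    sep = _sniff_delimiter(first)
    has_header = not _is_numeric_row(first.strip(), sep)
    engine = "c" if sep in ("\t", ",") else "python"
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if has_header else None,
            engine=engine,
            comment="#",
        )
    except pd.errors.ParserError as exc:
        raise ChronoamperogramFormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.empty:
        raise ChronoamperogramFormatError(f"{path}: no data rows")

    # Locate any non-numeric or missing cell precisely before failing.
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    for c in bad_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            col = list(df.columns).index(c)
            raise ChronoamperogramFormatError(
                f"{path}: non-numeric value {df[c][row]!r} at data row {row}, column {col}"
            )
        df[c] = coerced
    if df.isna().any().any():
        col_has = df.isna().any()
        col = next(c for c in df.columns if col_has[c])
        row = int(df[col].isna().idxmax())
        raise ChronoamperogramFormatError(
            f"{path}: missing value at data row {row}, column {list(df.columns).index(col)}"
        )

    values = df.to_numpy(dtype=float)
    if transpose:
        values = values.T
        channel_ids = [f"ch{i + 1}" for i in range(values.shape[1])]
    elif has_header:
        channel_ids = [str(c) for c in df.columns]
    else:
        channel_ids = [f"ch{i + 1}" for i in range(values.shape[1])]

    rec = Chronoamperogram(values / config.gain, config.sampling_rate, channel_ids)
    if config.selected_channels is not None:
        rec = rec.select(list(config.selected_channels))
    return rec


def write_chronoamperogram(rec: Chronoamperogram, path, fmt: str = "%.6g") -> None:
    """Write a recording in the canonical tab-separated dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_ids) + "\n")
        np.savetxt(fh, rec.samples, fmt=fmt, delimiter="\t")


#: Deterministic column order of the per-spike report.
SPIKE_REPORT_COLUMNS = [
    "channel",
    "spike_id",
    "start_ms",
    "apex_ms",
    "end_ms",
    "i_max_pA",
    "duration_ms",
    "q_pC",
    "n_molecules",
    "t_half_ms",
    "rise_slope_pA_per_ms",
    "rise_time_ms",
    "decay_model",
    "decay_tau1_ms",
    "decay_tau2_ms",
    "decay_amp1_pA",
    "decay_amp2_pA",
    "decay_sse_pA2",
    "baseline_slope_pA_per_ms",
    "baseline_intercept_pA",
    "threshold_pA",
    "flags",
    "foot_present",
    "foot_start_ms",
    "foot_end_ms",
    "i_foot_pA",
    "t_foot_ms",
    "q_foot_pC",
]

FOOT_REPORT_COLUMNS = [
    "channel",
    "spike_id",
    "foot_start_ms",
    "foot_end_ms",
    "i_foot_pA",
    "t_foot_ms",
    "q_foot_pC",
]


def _spike_row(spike) -> dict:
    return {
        "channel": spike.channel_id,
        "spike_id": spike.spike_id,
        "start_ms": spike.start_ms,
        "apex_ms": spike.apex_ms,
        "end_ms": spike.end_ms,
        "i_max_pA": spike.i_max,
        "duration_ms": spike.duration_ms,
        "q_pC": spike.charge_q,
        "n_molecules": spike.n_molecules,
        "t_half_ms": spike.t_half,
        "rise_slope_pA_per_ms": spike.rise_slope,
        "rise_time_ms": spike.rise_time,
        "decay_model": spike.decay_model,
        "decay_tau1_ms": spike.decay_tau1,
        "decay_tau2_ms": spike.decay_tau2,
        "decay_amp1_pA": spike.decay_amp1,
        "decay_amp2_pA": spike.decay_amp2,
        "decay_sse_pA2": spike.decay_sse,
        "baseline_slope_pA_per_ms": spike.baseline_slope,
        "baseline_intercept_pA": spike.baseline_intercept,
        "threshold_pA": spike.threshold_pA,
        "flags": ";".join(spike.flags),
    }


def _foot_row(foot) -> dict:
    return {
        "channel": foot.channel_id,
        "spike_id": foot.spike_id,
        "foot_start_ms": foot.foot_start_ms,
        "foot_end_ms": foot.foot_end_ms,
        "i_foot_pA": foot.i_foot,
        "t_foot_ms": foot.t_foot,
        "q_foot_pC": foot.q_foot,
    }


def write_spike_report(spikes, feet, path) -> None:
    """Write one CSV row per spike with its foot columns joined in.

    Foot columns are empty (``foot_present`` false) for spikes without a
    detected pre-spike foot.  Column order is fixed so repeated runs on
    identical inputs are byte-identical.
    """
    feet_by_key = {(f.channel_id, f.spike_id): f for f in (feet or [])}
    rows = []
    for s in spikes:
        row = _spike_row(s)
        foot = feet_by_key.get((s.channel_id, s.spike_id))
        row["foot_present"] = foot is not None
        if foot is not None:
            row.update(
                foot_start_ms=foot.foot_start_ms,
                foot_end_ms=foot.foot_end_ms,
                i_foot_pA=foot.i_foot,
                t_foot_ms=foot.t_foot,
                q_foot_pC=foot.q_foot,
            )
        rows.append(row)
    df = pd.DataFrame(rows, columns=SPIKE_REPORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")


def write_feet_report(feet, path) -> None:
    """Write the stand-alone feet CSV (one row per detected foot)."""
    df = pd.DataFrame([_foot_row(f) for f in feet], columns=FOOT_REPORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")
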