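"""Reading, validation and resampling of multichannel ACM recordings.

An ambulatory circadian monitoring (ACM) recording carries four channels at
their native logger rates: wrist skin temperature (one sample / 10 min),
arm acceleration, arm tilt and environmental light (one sample / 30 s).
This module parses logger-style delimited text exports, places all channels
on a common epoch grid trimmed to whole local-clock days, and collapses an
epoched channel into its average 24-h waveform (mean +/- SEM over days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel names, in export order
CHANNELS = ("temperature", "activity", "position", "light")

#: maximum gap bridged by step interpolation, seconds
MAX_FFILL_SECONDS = 30 * 60

#: maximum tolerated fraction of missing epochs per channel
MAX_MISSING_FRACTION = 0.20

SECONDS_PER_DAY = 86_400


@dataclass
class RawRecording:
    """Per-subject multichannel samples at native rates.

    Each channel is a ``pandas.Series`` of values indexed by naive local
    timestamps, strictly increasing.
    """

    subject_id: str
    channels: dict[str, pd.Series]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in self.channels.items():
            if not series.index.is_monotonic_increasing:
                raise ValueError(f"timestamps not increasing in channel {name!r}")


@dataclass
class EpochedRecording:
    """Channels resampled onto a common grid of whole days.

    ``data`` holds one column per channel on a regular ``DatetimeIndex``
    starting at a midnight; ``n`` is the total number of epochs and ``p``
    the number of epochs per day, so ``n == days * p`` exactly.  Epochs
    with no usable samples are NaN and counted in ``missing``.
    """

    subject_id: str
    epoch_length: int
    data: pd.DataFrame
    missing: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def days(self) -> int:
        return self.n // self.p

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    def values(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy(dtype=float)


@dataclass
class DailyWaveform:
    """Average 24-h profile of one channel: bin means +/- SEM over days."""

    bin_length: int
    values: np.ndarray
    sem: np.ndarray
    n_days: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_midpoint_minutes(self, bin_index: int) -> float:
        """Clock time (minutes from midnight) at the centre of a bin."""
        return ((bin_index + 0.5) * self.bin_length / 60.0) % 1440.0


def read_channel_file(path: str | Path) -> tuple[pd.Series, int]:
    """Parse one logger export: header line, then timestamp/value rows.

    Delimiter (comma or tab) is auto-detected.  Rows whose timestamp or
    value fail to parse are dropped; the count of dropped rows is returned
    alongside the series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=None, engine="python", header=0, dtype=str)
    if table.empty or table.shape[1] < 2:
        raise ValueError(f"empty or malformed channel file: {path}")
    stamps = pd.to_datetime(table.iloc[:, 0], errors="coerce", format="ISO8601")

    def parse_float(s: str) -> float:  # correctly-rounded, unlike the fast parser
        try:
            return float(s)
        except (TypeError, ValueError):
            return float("nan")

    values = table.iloc[:, 1].map(parse_float)
    good = stamps.notna() & values.notna()
    dropped = int((~good).sum())
    series = pd.Series(
        values[good].to_numpy(), index=pd.DatetimeIndex(stamps[good], name=None)
    )
    series.index.name = None
    if series.empty:
        raise ValueError(f"no parseable rows in channel file: {path}")
    return series.sort_index(), dropped


def read_recording(
    paths: Mapping[str, str | Path], subject_id: str = "subject"
) -> RawRecording:
    """Load the four ACM channels from per-channel delimited text files."""
    channels: dict[str, pd.Series] = {}
    dropped: dict[str, int] = {}
    for name in CHANNELS:
        if name not in paths:
            raise ValueError(f"missing channel: {name}")
        channels[name], dropped[name] = read_channel_file(paths[name])
        if dropped[name]:
            logger.warning(
                "channel %s: dropped %d unparseable rows", name, dropped[name]
            )
    return RawRecording(subject_id, channels, metadata={"dropped_rows": dropped})


def write_recording(rec: RawRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write one delimited text file per channel (timestamp, value)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, series in rec.channels.items():
        path = out_dir / f"{rec.subject_id}_{name}.csv"
        frame = pd.DataFrame(
            {
                "timestamp": series.index.strftime("%Y-%m-%dT%H:%M:%S"),
                "value": [format(v, ".17g") for v in series.to_numpy()],
            }
        )
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def _common_whole_day_span(rec: RawRecording) -> tuple[pd.Timestamp, int]:
    """First midnight and whole-day count common to all channels."""
    start = max(s.index[0] for s in rec.channels.values())
    end = min(s.index[-1] for s in rec.channels.values())
    first_midnight = start.normalize()
    if first_midnight < start:
        first_midnight += pd.Timedelta(days=1)
    # a sample at e.g. 23:59:30 still covers the tail of its day: round the
    # end up to the next midnight when the remainder is within the fill
    # tolerance, otherwise trim the partial day
    last_midnight = end.normalize()
    if end != last_midnight and (end.ceil("D") - end) <= pd.Timedelta(
        seconds=MAX_FFILL_SECONDS
    ):
        last_midnight = end.ceil("D")
    days = (last_midnight - first_midnight).days
    return first_midnight, days


def to_common_grid(rec: RawRecording, epoch_length: int = 30) -> EpochedRecording:
    """Resample all channels onto one epoch grid of whole days.

    Samples are averaged within each epoch; channels sampled coarser than
    the grid are carried forward (step interpolation).  Gaps are bridged
    by forward fill up to 30 min (the leading edge of day one may be
    back-filled by the same margin); anything longer stays NaN and is
    counted as missing.  Leading/trailing partial days are trimmed.
    """
    if SECONDS_PER_DAY % epoch_length:
        raise ValueError("epoch_length must divide 86400 s")
    first_midnight, days = _common_whole_day_span(rec)
    if days < 2:
        raise ValueError(
            f"recording spans only {days} whole day(s); at least 2 required"
        )
    p = SECONDS_PER_DAY // epoch_length
    grid = pd.date_range(first_midnight, periods=days * p, freq=f"{epoch_length}s")
    limit = max(1, MAX_FFILL_SECONDS // epoch_length)
    columns: dict[str, pd.Series] = {}
    missing: dict[str, int] = {}
    for name, series in rec.channels.items():
        binned = series.groupby(series.index.floor(f"{epoch_length}s")).mean()
        col = binned.reindex(grid)
        col = col.ffill(limit=limit).bfill(limit=limit)
        n_missing = int(col.isna().sum())
        frac = n_missing / len(col)
        if frac > MAX_MISSING_FRACTION:
            raise ValueError(
                f"channel {name}: {frac:.0%} epochs missing exceeds "
                f"{MAX_MISSING_FRACTION:.0%}"
            )
        columns[name] = col
        missing[name] = n_missing
    data = pd.DataFrame(columns, index=grid)
    return EpochedRecording(
        rec.subject_id, epoch_length, data, missing, dict(rec.metadata)
    )


def average_day(
    epoched: EpochedRecording, channel: str, bin_length: int = 600
) -> DailyWaveform:
    """Collapse an epoched channel into its mean 24-h waveform.

    Bin ``h`` holds the mean over days of the values falling in clock-time
    bin ``h`` (bin 0 starts at 00:00) with the SEM over day means; days
    with no valid data in a bin do not contribute there.
    """
    if SECONDS_PER_DAY % bin_length:
        raise ValueError("bin_length must divide 86400 s")
    if bin_length % epoched.epoch_length:
        raise ValueError("bin_length must be a multiple of the epoch length")
    n_bins = SECONDS_PER_DAY // bin_length
    per_bin = bin_length // epoched.epoch_length
    x = epoched.values(channel).reshape(epoched.days, n_bins, per_bin)
    with np.errstate(invalid="ignore"):
        day_bin = np.nanmean(x, axis=2)  # (days, bins)
        values = np.nanmean(day_bin, axis=0)
        n_days = np.sum(np.isfinite(day_bin), axis=0)
        sd = np.nanstd(day_bin, axis=0, ddof=1) if epoched.days > 1 else np.zeros(n_bins)
    sem = np.where(n_days > 1, sd / np.sqrt(np.maximum(n_days, 1)), 0.0)
    return DailyWaveform(bin_length, values, sem, n_days)


def rebin(epoched: EpochedRecording, channel: str, bin_length: int = 3600) -> np.ndarray:
    """Within-day rebinned series (e.g. hourly means) as a flat array."""
    if bin_length % epoched.epoch_length or SECONDS_PER_DAY % bin_length:
        raise ValueError("bin_length must be a multiple of epoch length dividing 86400")
    per_bin = bin_length // epoched.epoch_length
    x = epoched.values(channel).reshape(-1, per_bin)
    with np.errstate(invalid="ignore"):
        return np.nanmean(x, axis=1)


def write_epoched(epoched: EpochedRecording, path: str | Path) -> Path:
    """Single-table export: epoch index, clock time, one column per channel."""
    path = Path(path)
    out = epoched.data.copy()
    out.insert(0, "clock_time", epoched.data.index.strftime("%H:%M:%S"))
    out.insert(0, "timestamp", epoched.data.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index_label="epoch", float_format="%.10g")
    return path
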