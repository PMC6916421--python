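"""TAP integration and sleep estimation.

TAP combines the three body channels into a single 0-1 activation level:
wrist Temperature (normalized to its 5th-95th percentile span and
inverted, because distal skin temperature rises during sleep), Activity
(normalized to its 95th percentile) and arm Position (tilt normalized
from horizontal to vertical).  TAP is 0 at minimal activation (warm,
still, horizontal — sleep-like) and 1 at maximal activation.

Sleep is then scored per epoch by comparing TAP against a threshold
established dynamically for each subject from their own rhythm: the
midpoint of the TAP L5v (nocturnal floor) and M10v (diurnal plateau) of
the subject's average day, followed by a 30-min median filter that
removes isolated flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .io import EpochedRecording
from .nonparam import average_day, extreme_window


@dataclass
class SleepEstimate:
    """Binary per-epoch sleep indicator (1 = sleep) and the threshold used."""

    values: np.ndarray
    threshold: float


def normalize_temperature(
    series: np.ndarray, p5: float | None = None, p95: float | None = None
) -> np.ndarray:
    """Inverted 0-1 temperature: 1 at/below the 5th percentile reference.

    t_inv = 1 - clamp((x - p5) / (p95 - p5), 0, 1).  Percentile anchors
    default to the subject's own series (over the whole recording).
    """
    x = np.asarray(series, dtype=float)
    if p5 is None:
        p5 = float(np.nanpercentile(x, 5))
    if p95 is None:
        p95 = float(np.nanpercentile(x, 95))
    if p95 <= p5:
        raise ValueError("temperature percentiles degenerate (constant series?)")
    return 1.0 - np.clip((x - p5) / (p95 - p5), 0.0, 1.0)


def normalize_activity(series: np.ndarray, p95: float | None = None) -> np.ndarray:
    """0-1 activity: 0 = total immobility, 1 = the 95th-percentile reference."""
    x = np.asarray(series, dtype=float)
    if p95 is None:
        p95 = float(np.nanpercentile(x, 95))
    if p95 <= 0:
        raise ValueError("activity reference percentile is zero (all-zero series?)")
    return np.clip(x / p95, 0.0, 1.0)


def normalize_position(tilt: np.ndarray) -> np.ndarray:
    """0-1 arm position: 0 = horizontal, 1 = vertical (tilt in degrees)."""
    return np.clip(np.abs(np.asarray(tilt, dtype=float)) / 90.0, 0.0, 1.0)


def compute_tap(
    t_inv: np.ndarray, a_norm: np.ndarray, p_norm: np.ndarray
) -> np.ndarray:
    """Equal-weight combination of the three normalized channels.

    TAP = (t_inv + a_norm + p_norm) / 3, so TAP = 0 exactly when all
    three are 0 and TAP = 1 exactly when all three are 1.
    """
    t_inv, a_norm, p_norm = (np.asarray(c, dtype=float) for c in (t_inv, a_norm, p_norm))
    if not t_inv.shape == a_norm.shape == p_norm.shape:
        raise ValueError("normalized channels must share one grid")
    return (t_inv + a_norm + p_norm) / 3.0


def add_tap(epoched: EpochedRecording) -> EpochedRecording:
    """Append a ``tap`` column computed from the three body channels."""
    t_inv = normalize_temperature(epoched.values("temperature"))
    a_norm = normalize_activity(epoched.values("activity"))
    p_norm = normalize_position(epoched.values("position"))
    epoched.data["tap"] = compute_tap(t_inv, a_norm, p_norm)
    return epoched


def estimate_sleep(
    epoched: EpochedRecording,
    channel: str = "tap",
    smooth_seconds: int = 1800,
) -> SleepEstimate:
    """Score each epoch sleep/wake from TAP with a per-subject threshold.

    The threshold is the midpoint of the subject's TAP-L5v and TAP-M10v
    (from the average-day waveform), which is scale-free and lies
    strictly between the nightly floor and the daily plateau; epochs with
    TAP below it are scored as sleep.  A circular median filter of
    ``smooth_seconds`` (default 30 min) removes isolated flips.
    """
    tap = epoched.values(channel)
    finite = tap[np.isfinite(tap)]
    if finite.size == 0 or np.nanmax(tap) <= np.nanmin(tap):
        raise ValueError("sleep threshold undefined for constant TAP")
    wf_bin = 600 if epoched.epoch_length <= 600 else epoched.epoch_length
    wf = average_day(epoched, channel, wf_bin)
    l5v, _ = extreme_window(wf, 5, "min")
    m10v, _ = extreme_window(wf, 10, "max")
    threshold = (l5v + m10v) / 2.0
    sleep = (tap < threshold).astype(float)
    size = max(1, smooth_seconds // epoched.epoch_length)
    if size % 2 == 0:
        size += 1
    if size > 1:
        sleep = median_filter(sleep, size=size, mode="wrap")
    return SleepEstimate(values=sleep, threshold=float(threshold))


def add_sleep(epoched: EpochedRecording) -> EpochedRecording:
    """Append a binary ``sleep`` column estimated from the ``tap`` column."""
    if "tap" not in epoched.data:
        add_tap(epoched)
    est = estimate_sleep(epoched)
    epoched.data["sleep"] = est.values
    epoched.metadata["sleep_threshold"] = est.threshold
    return epoched
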