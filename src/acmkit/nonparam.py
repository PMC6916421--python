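"""Non-parametric circadian rhythm indexes.

Implements the classic non-parametric toolkit for any epoched circadian
variable: the extreme-window markers (M10/M5 and L10/L5 values and their
midpoint clock times), interdaily stability (IS), intradaily variability
(IV), relative amplitude (RA) in both orientations, and the composite
circadian function index (CFI).

Orientation conventions
-----------------------
Activity, position, TAP and light peak during wakefulness, so their
amplitude contrast is RA = (M10v - L5v) / (M10v + L5v).  Wrist temperature
and the sleep indicator peak during sleep, so their contrast is computed
from the nocturnal M5 and diurnal L10 windows, RA = (M5v - L10v) /
(L10v + M5v); the temperature RA is additionally amplified x10 (clamped to
1) so that it spans the 0-1 scale.  CFI always combines the un-amplified
RA so that all three of its components live on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DailyWaveform, EpochedRecording, average_day, rebin

#: variable roles whose profile peaks at night (sleep-oriented)
NOCTURNAL_ROLES = frozenset({"temperature", "sleep"})

VALID_ROLES = ("temperature", "activity", "position", "tap", "sleep", "light")


@dataclass
class NonParamIndexes:
    """Window markers and rhythm indexes for one variable.

    Window midpoint times (``*h``) are clock times in minutes from
    midnight, circular on [0, 1440).
    """

    variable: str
    m10v: float
    m10h: float
    m5v: float
    m5h: float
    l10v: float
    l10h: float
    l5v: float
    l5h: float
    IS: float
    IV: float
    RA: float
    CFI: float


def extreme_window(
    waveform: DailyWaveform, width_hours: float, mode: str
) -> tuple[float, float]:
    """Best window of ``width_hours`` consecutive hours on the average day.

    Scans every circular window start bin exhaustively and returns the
    window mean together with the clock time (minutes from midnight) of
    the window centre.  Ties are broken by the earliest start scanning
    from 00:00.

    Parameters
    ----------
    mode : {"max", "min"}
        Whether the window of maximal (M) or lowest (L) mean is sought.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    width_s = int(round(width_hours * 3600))
    if width_s % waveform.bin_length:
        raise ValueError("window width must span a whole number of bins")
    w = width_s // waveform.bin_length
    x = np.asarray(waveform.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform has missing bins; impute first")
    nb = len(x)
    if not 0 < w <= nb:
        raise ValueError("window width must be positive and at most 24 h")
    # circular window means for every start bin
    doubled = np.concatenate([x, x[: w - 1]])
    csum = np.concatenate([[0.0], np.cumsum(doubled)])
    means = (csum[w:] - csum[:-w]) / w
    # earliest-start tie-break, robust to cumsum rounding drift
    tol = 1e-9 * max(1.0, float(np.abs(means).max()))
    if mode == "min":
        start = int(np.argmax(means <= means.min() + tol))
    else:
        start = int(np.argmax(means >= means.max() - tol))
    midpoint = (start * waveform.bin_length + width_s / 2) / 60.0 % 1440.0
    return float(means[start]), float(midpoint)


def interdaily_stability(values: np.ndarray, bins_per_day: int) -> float:
    """Day-to-day repeatability of the daily waveform, on [0, 1].

    IS = [n * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2],
    where the numerator sums over the p time-of-day bins.  IS is 1 when
    the daily wave repeats exactly across days and tends to 0 for noise.
    """
    x = np.asarray(values, dtype=float)
    if x.size % bins_per_day:
        raise ValueError("series length must be a whole number of days")
    if x.size // bins_per_day < 2:
        raise ValueError("IS requires at least 2 days")
    finite = np.isfinite(x)
    n = int(finite.sum())
    grand = np.nanmean(x)
    denom = np.nansum((x - grand) ** 2)
    if denom == 0:
        raise ValueError("IS undefined for constant signal")
    day_shape = x.reshape(-1, bins_per_day)
    with np.errstate(invalid="ignore"):
        bin_means = np.nanmean(day_shape, axis=0)
    num = np.nansum((bin_means - grand) ** 2)
    return float(n * num / (bins_per_day * denom))


def intradaily_variability(values: np.ndarray) -> float:
    """Rhythm fragmentation from squared consecutive differences.

    IV = [n * sum_{i=2..n} (x_i - x_{i-1})^2] / [(n-1) * sum_i (x_i - xbar)^2].
    Close to 0 for a smooth sinusoid, around 2 for white Gaussian noise;
    no upper clamp is applied here (only inside CFI).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("IV requires at least 2 samples")
    denom = np.sum((x - x.mean()) ** 2)
    if denom == 0:
        raise ValueError("IV undefined for constant signal")
    num = np.sum(np.diff(x) ** 2)
    return float(n * num / ((n - 1) * denom))


def relative_amplitude(high: float, low: float, variant: str = "standard") -> float:
    """Rest-activity contrast (high - low) / (high + low) on [0, 1].

    ``variant``: "standard" for wake-peaking variables (high = M10v,
    low = L5v), "inverted" for sleep-peaking ones (high = M5v,
    low = L10v), "temperature" as inverted with the x10 amplification
    (clamped to 1) applied to the wrist-temperature contrast.
    """
    if variant not in ("standard", "inverted", "temperature"):
        raise ValueError(f"unknown RA variant: {variant}")
    if high < low:
        raise ValueError("high window mean below low window mean")
    if high + low <= 0:
        raise ValueError("RA undefined: high + low must be positive")
    ra = (high - low) / (high + low)
    if variant == "temperature":
        ra = min(ra * 10.0, 1.0)
    return float(ra)


def circadian_function_index(IS: float, IV: float, RA: float) -> float:
    """Composite rhythm-robustness score on [0, 1].

    CFI = (IS + (1 - min(IV, 2)/2) + RA) / 3: the mean of IS, inverted
    IV normalized by its Gaussian-noise ceiling of 2, and RA.  1 means a
    maximally robust rhythm, 0 null circadian rhythmicity.
    """
    eps = 1e-9
    if not -eps <= IS <= 1 + eps:
        raise ValueError("IS must lie in [0, 1]")
    if IV < -eps:
        raise ValueError("IV must be non-negative")
    if not -eps <= RA <= 1 + eps:
        raise ValueError("RA must lie in [0, 1]")
    return float((IS + (1.0 - min(IV, 2.0) / 2.0) + RA) / 3.0)


def _impute_waveform(wf: DailyWaveform) -> DailyWaveform:
    """Fill empty waveform bins by circular linear interpolation."""
    x = np.asarray(wf.values, dtype=float)
    if np.all(np.isfinite(x)):
        return wf
    idx = np.arange(len(x))
    good = np.isfinite(x)
    if not good.any():
        raise ValueError("waveform entirely missing")
    filled = np.interp(idx, idx[good], x[good], period=len(x))
    return DailyWaveform(wf.bin_length, filled, wf.sem, wf.n_days)


def summarize_variable(
    epoched: EpochedRecording,
    channel: str,
    role: str | None = None,
    waveform_bin: int = 600,
    stability_bin: int = 3600,
) -> NonParamIndexes:
    """All non-parametric indexes for one epoched channel.

    Windows are searched on the subject's average-day waveform
    (``waveform_bin``, default 10 min, giving minute-scale phase times);
    IS and IV are computed on within-day rebinned means
    (``stability_bin``, default hourly).  Light is analysed on the
    log10(lux + 1) scale.  The RA orientation and the CFI's un-amplified
    RA follow the role conventions in the module docstring.
    """
    role = role or channel
    if role not in VALID_ROLES:
        raise ValueError(f"unknown variable role: {role}")
    if role == "light":
        data = epoched.data.copy()
        data[channel] = np.log10(np.maximum(data[channel], 0.0) + 1.0)
        epoched = EpochedRecording(
            epoched.subject_id, epoched.epoch_length, data, epoched.missing
        )
    wf = _impute_waveform(average_day(epoched, channel, waveform_bin))
    m10v, m10h = extreme_window(wf, 10, "max")
    l10v, l10h = extreme_window(wf, 10, "min")
    m5v, m5h = extreme_window(wf, 5, "max")
    l5v, l5h = extreme_window(wf, 5, "min")

    hourly = rebin(epoched, channel, stability_bin)
    bins_per_day = 86_400 // stability_bin
    IS = interdaily_stability(hourly, bins_per_day)
    IV = intradaily_variability(hourly)

    if role in NOCTURNAL_ROLES:
        variant = "temperature" if role == "temperature" else "inverted"
        RA = relative_amplitude(m5v, l10v, variant)
        ra_for_cfi = relative_amplitude(m5v, l10v, "inverted")
    else:
        RA = relative_amplitude(m10v, l5v, "standard")
        ra_for_cfi = RA
    CFI = circadian_function_index(min(IS, 1.0), IV, min(ra_for_cfi, 1.0))
    return NonParamIndexes(
        variable=role,
        m10v=m10v,
        m10h=m10h,
        m5v=m5v,
        m5h=m5h,
        l10v=l10v,
        l10h=l10h,
        l5v=l5v,
        l5h=l5h,
        IS=IS,
        IV=IV,
        RA=RA,
        CFI=CFI,
    )


def circular_mean_minutes(times: np.ndarray) -> float:
    """Circular mean of clock times in minutes from midnight.

    Needed when averaging phase markers across subjects whose sleep
    midpoints straddle midnight (typical for delayed phases).
    """
    theta = np.asarray(times, dtype=float) * 2 * np.pi / 1440.0
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float(mean * 1440.0 / (2 * np.pi) % 1440.0)
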