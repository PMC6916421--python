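"""Synthetic 7-day multichannel ACM recordings per diagnostic phenotype.

Generates labelled wrist recordings (temperature every 10 min; activity,
position and light every 30 s) for five phenotypes — healthy control,
onset insomnia, maintenance insomnia, mild insomnia and delayed sleep
phase disorder (DSPD) — so that the full analysis chain can be exercised
and validated without access to a clinical database.

The generative model is deliberately minimal:

* per-night sleep episodes with Gaussian jitter of mid-sleep time and
  duration around the phenotype means, plus Poisson-count nocturnal
  awakenings with exponential durations;
* wake activity modulated by a raised-cosine daytime envelope centred on
  the phenotype's activation peak (this is what places the M10 phase);
* wrist temperature as a square wave between wake and sleep levels
  smoothed by a first-order exponential response (30-min time constant)
  with Gaussian measurement noise;
* daytime light following a solar arc, near darkness at night, with the
  DSPD phenotype additionally exposed to evening artificial light while
  awake.

Identical (preset, days, seed) inputs give bitwise-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import RawRecording, write_recording

CLASSES = (
    "control",
    "mild_insomnia",
    "maintenance_insomnia",
    "onset_insomnia",
    "dspd",
)

#: simulation step, seconds (native rate of the 30-s channels)
STEP_SECONDS = 30
STEPS_PER_DAY = 86_400 // STEP_SECONDS
TEMP_PERIOD_STEPS = 600 // STEP_SECONDS  # temperature logged every 10 min

#: peak wake acceleration scale, m/s^2
WAKE_ACTIVITY_SCALE = 1.2
#: first-order temperature response time constant, minutes
TEMP_TAU_MIN = 30.0

_WAKE, _SLEEP, _AWAKENING, _REST = 0, 1, 2, 3


@dataclass(frozen=True)
class PhenotypePreset:
    """Generative parameters of one diagnostic phenotype.

    Clock times are minutes from midnight (circular); durations are in
    minutes, temperatures in deg C, light in lux.
    """

    label: str
    mid_sleep_mean: float
    mid_sleep_sd_across_days: float
    sleep_duration_mean: float
    n_awakenings_per_night: float
    awakening_duration_mean: float
    wake_activity_level: float
    activation_peak_mean: float
    temp_sleep_mean: float
    temp_wake_mean: float
    temp_noise_sd: float
    evening_light: bool
    day_light_level: float
    sleep_duration_sd: float = 20.0
    nap_probability: float = 0.0  # chance of an afternoon nap per day
    nap_duration_mean: float = 50.0
    sleep_latency_mean: float = 15.0  # minutes in bed awake before sleep onset

    def __post_init__(self) -> None:
        if not 0 <= self.mid_sleep_mean < 1440:
            raise ValueError("mid_sleep_mean must lie in [0, 1440)")
        if self.sleep_duration_mean <= 0 or self.awakening_duration_mean <= 0:
            raise ValueError("durations must be positive")
        if min(
            self.mid_sleep_sd_across_days,
            self.sleep_duration_sd,
            self.temp_noise_sd,
            self.n_awakenings_per_night,
        ) < 0:
            raise ValueError("rates and standard deviations must be non-negative")
        if not 0 < self.wake_activity_level <= 1:
            raise ValueError("wake_activity_level must lie in (0, 1]")


def phenotype_presets() -> dict[str, PhenotypePreset]:
    """Default presets for the five diagnostic classes.

    Calibrated so the downstream pipeline recovers the qualitative class
    geometry: control mid-sleep near 3:54 with robust, stable rhythms;
    mild insomnia differing from controls only in reduced sleep-rhythm
    stability; maintenance insomnia with heavily fragmented sleep (low
    TAP relative amplitude); onset insomnia with delayed mid-sleep but a
    normal mid-afternoon activation peak; DSPD with both mid-sleep
    (6:48) and activation peak delayed, plus evening light exposure.
    """
    return {
        "control": PhenotypePreset(
            label="control",
            mid_sleep_mean=234.0,  # 3:54
            mid_sleep_sd_across_days=20.0,
            sleep_duration_mean=480.0,
            n_awakenings_per_night=0.5,
            awakening_duration_mean=8.0,
            wake_activity_level=0.9,
            activation_peak_mean=976.0,  # 16:16
            temp_sleep_mean=35.0,
            temp_wake_mean=32.2,
            temp_noise_sd=0.25,
            evening_light=False,
            day_light_level=250.0,
        ),
        "mild_insomnia": PhenotypePreset(
            label="mild_insomnia",
            mid_sleep_mean=240.0,  # 4:00
            mid_sleep_sd_across_days=70.0,
            sleep_duration_mean=440.0,
            sleep_duration_sd=90.0,
            n_awakenings_per_night=1.2,
            awakening_duration_mean=10.0,
            nap_probability=0.8,  # irregular daytime dozing
            wake_activity_level=0.9,
            activation_peak_mean=970.0,
            temp_sleep_mean=34.8,
            temp_wake_mean=32.3,
            temp_noise_sd=0.3,
            evening_light=False,
            day_light_level=220.0,
        ),
        "maintenance_insomnia": PhenotypePreset(
            label="maintenance_insomnia",
            mid_sleep_mean=225.0,  # 3:45
            mid_sleep_sd_across_days=45.0,
            sleep_duration_mean=480.0,
            n_awakenings_per_night=7.0,
            awakening_duration_mean=35.0,
            wake_activity_level=0.85,
            activation_peak_mean=925.0,  # 15:25
            temp_sleep_mean=34.6,
            temp_wake_mean=32.4,
            temp_noise_sd=0.3,
            evening_light=False,
            day_light_level=200.0,
        ),
        "onset_insomnia": PhenotypePreset(
            label="onset_insomnia",
            mid_sleep_mean=385.0,  # 6:25
            mid_sleep_sd_across_days=45.0,
            sleep_duration_mean=280.0,
            sleep_duration_sd=30.0,
            sleep_latency_mean=240.0,  # hours in bed before falling asleep
            n_awakenings_per_night=1.5,
            awakening_duration_mean=10.0,
            wake_activity_level=0.85,
            activation_peak_mean=820.0,  # 13:40, earlier than the 16:07 cut
            temp_sleep_mean=34.6,
            temp_wake_mean=32.4,
            temp_noise_sd=0.3,
            evening_light=False,
            day_light_level=200.0,
        ),
        "dspd": PhenotypePreset(
            label="dspd",
            mid_sleep_mean=408.0,  # 6:48
            mid_sleep_sd_across_days=50.0,
            sleep_duration_mean=480.0,
            n_awakenings_per_night=1.0,
            awakening_duration_mean=10.0,
            wake_activity_level=0.85,
            activation_peak_mean=1087.0,  # 18:07
            temp_sleep_mean=34.7,
            temp_wake_mean=32.4,
            temp_noise_sd=0.3,
            evening_light=True,
            day_light_level=180.0,
        ),
    }


@dataclass
class CohortSpec:
    """Requested cohort composition: subjects per class, seed, days."""

    counts: dict[str, int] = field(
        default_factory=lambda: {label: 10 for label in CLASSES}
    )
    seed: int = 1
    days: int = 7

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.days < 2:
            raise ValueError("at least 2 days required (IS needs >= 2 days)")
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if sum(self.counts.values()) == 0:
            raise ValueError("at least one class count must be positive")


def _sleep_state(
    preset: PhenotypePreset, days: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-30-s state: 0 wake, 1 sleep, 2 nocturnal awakening, 3 in bed awake."""
    n = days * STEPS_PER_DAY
    state = np.full(n, _WAKE, dtype=np.int8)
    # night d has its mid-sleep in the early hours of day d; d = 0..days
    # covers the episode truncated at the recording start and the final
    # evening's sleep onset.
    for d in range(days + 1):
        mid = d * 1440.0 + rng.normal(preset.mid_sleep_mean, preset.mid_sleep_sd_across_days)
        dur = max(60.0, rng.normal(preset.sleep_duration_mean, preset.sleep_duration_sd))
        onset, offset = mid - dur / 2.0, mid + dur / 2.0
        latency = max(5.0, rng.normal(preset.sleep_latency_mean, preset.sleep_latency_mean / 3))
        r0 = max(0, int(round((onset - latency) * 60 / STEP_SECONDS)))
        i0 = max(0, int(round(onset * 60 / STEP_SECONDS)))
        i1 = min(n, int(round(offset * 60 / STEP_SECONDS)))
        if min(i0, n) > r0:
            state[r0:min(i0, n)] = _REST
        if i1 > i0:
            state[i0:i1] = _SLEEP
        k = rng.poisson(preset.n_awakenings_per_night)
        for _ in range(k):
            a_start = rng.uniform(onset + 10.0, offset - 10.0)
            a_dur = float(np.clip(rng.exponential(preset.awakening_duration_mean), 3.0, 90.0))
            j0 = max(0, int(round(a_start * 60 / STEP_SECONDS)))
            j1 = min(n, int(round((a_start + a_dur) * 60 / STEP_SECONDS)))
            mask = state[j0:j1] == _SLEEP
            state[j0:j1][mask] = _AWAKENING
    return state


def generate_subject(
    preset: PhenotypePreset,
    days: int = 7,
    seed: int = 0,
    subject_id: str | None = None,
    start: str = "2024-01-01",
    nap_probability: float = 0.0,
    removal_probability: float = 0.0,
) -> RawRecording:
    """Simulate one subject's 7-day four-channel recording.

    Masking events are off by default: ``nap_probability`` adds an
    early-afternoon sleep bout per day with that probability, and
    ``removal_probability`` a 1-2 h device-off interval per day (activity
    zero, position flat, temperature drifting to ambient).

    The true simulated sleep indicator (30-s grid) is kept in
    ``metadata["true_sleep"]`` for parameter-recovery checks.
    """
    if days < 2:
        raise ValueError("at least 2 days required (IS undefined for one day)")
    rng = np.random.default_rng(seed)
    n = days * STEPS_PER_DAY
    t_min = np.arange(n) * (STEP_SECONDS / 60.0)
    clock = t_min % 1440.0

    state = _sleep_state(preset, days, rng)
    nap_p = max(nap_probability, preset.nap_probability)
    if nap_p > 0:
        for d in range(days):
            if rng.random() < nap_p:
                nap_start = d * 1440.0 + rng.uniform(13 * 60, 17 * 60)
                nap_dur = rng.exponential(preset.nap_duration_mean)
                nap_dur = float(np.clip(nap_dur, 20.0, 120.0))
                j0 = int(round(nap_start * 60 / STEP_SECONDS))
                j1 = min(n, int(round((nap_start + nap_dur) * 60 / STEP_SECONDS)))
                state[j0:j1] = _SLEEP

    wake = state == _WAKE
    asleep = state == _SLEEP
    awakening = state == _AWAKENING
    resting = state == _REST  # in bed, awake

    # activity: raised-cosine daytime envelope centred on the activation peak
    cosf = 0.5 * (1.0 + np.cos(2 * np.pi * (clock - preset.activation_peak_mean) / 1440.0))
    envelope = 0.55 + 0.45 * cosf
    gamma = rng.gamma(2.0, 0.5, n)  # unit-mean multiplicative noise
    twitch = rng.exponential(0.01, n)
    fidget = rng.exponential(0.08, n)
    base = WAKE_ACTIVITY_SCALE * preset.wake_activity_level
    activity = np.where(
        wake,
        base * envelope * gamma,
        np.where(awakening, 0.5 * base * gamma, np.where(resting, fidget, twitch)),
    )

    # position: arm tilt in degrees
    tilt_noise = rng.normal(0.0, 15.0, n)
    sleep_tilt = np.abs(rng.normal(10.0, 8.0, n))
    rest_tilt = np.abs(rng.normal(14.0, 10.0, n))
    position = np.where(
        wake,
        60.0 + tilt_noise,
        np.where(awakening, 55.0 + tilt_noise, np.where(resting, rest_tilt, sleep_tilt)),
    )
    position = np.clip(position, 0.0, 90.0)

    # temperature: square target smoothed with a 30-min first-order response
    mid_temp = (preset.temp_sleep_mean + preset.temp_wake_mean) / 2.0
    target = np.where(
        asleep,
        preset.temp_sleep_mean,
        np.where(awakening | resting, mid_temp, preset.temp_wake_mean),
    )
    alpha = (STEP_SECONDS / 60.0) / TEMP_TAU_MIN
    temp, _ = lfilter(
        [alpha], [1.0, -(1.0 - alpha)], target, zi=[(1.0 - alpha) * target[0]]
    )

    # light: solar arc while awake; DSPD adds evening artificial light
    solar = np.clip(np.sin(np.pi * (clock - 420.0) / 840.0), 0.0, None)
    day_noise = rng.lognormal(0.0, 0.6, n)
    dark = rng.exponential(0.05, n)
    dim = rng.exponential(2.0, n)
    light = np.where(wake, preset.day_light_level * solar * day_noise + dark, dark)
    light = np.where(awakening | resting, dim, light)
    if preset.evening_light:
        night_awake = (wake | resting) & ((clock >= 20 * 60) | (clock < 6 * 60))
        light = light + np.where(night_awake, 120.0 * rng.lognormal(0.0, 0.3, n), 0.0)

    if removal_probability > 0:
        for d in range(days):
            if rng.random() < removal_probability:
                off_start = d * 1440.0 + rng.uniform(9 * 60, 19 * 60)
                off_dur = rng.uniform(60.0, 120.0)
                j0 = int(round(off_start * 60 / STEP_SECONDS))
                j1 = min(n, int(round((off_start + off_dur) * 60 / STEP_SECONDS)))
                activity[j0:j1] = 0.0
                position[j0:j1] = 0.0
                temp[j0:j1] = 30.0  # drifting toward ambient

    temp_sampled = temp[::TEMP_PERIOD_STEPS] + rng.normal(
        0.0, preset.temp_noise_sd, n // TEMP_PERIOD_STEPS
    )

    start_ts = pd.Timestamp(start)
    idx30 = pd.date_range(start_ts, periods=n, freq=f"{STEP_SECONDS}s")
    idx600 = pd.date_range(start_ts, periods=n // TEMP_PERIOD_STEPS, freq="600s")
    channels = {
        "temperature": pd.Series(np.clip(temp_sampled, 28.0, 37.0), index=idx600),
        "activity": pd.Series(np.maximum(activity, 0.0), index=idx30),
        "position": pd.Series(position, index=idx30),
        "light": pd.Series(np.maximum(light, 0.0), index=idx30),
    }
    subject_id = subject_id or f"{preset.label}_s{seed}"
    metadata = {
        "label": preset.label,
        "seed": seed,
        "true_sleep": pd.Series(asleep, index=idx30),
    }
    return RawRecording(subject_id, channels, metadata)


def generate_cohort(spec: CohortSpec) -> list[tuple[RawRecording, str]]:
    """Simulate a labelled cohort; per-subject seeds derive from the spec seed."""
    presets = phenotype_presets()
    total = sum(spec.counts.values())
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(total)
    cohort: list[tuple[RawRecording, str]] = []
    i = 0
    for label in CLASSES:
        for j in range(spec.counts.get(label, 0)):
            seed = int(child_seeds[i]) % (2**31)
            rec = generate_subject(
                presets[label], spec.days, seed, subject_id=f"{label}_{j:02d}"
            )
            cohort.append((rec, label))
            i += 1
    return cohort


def write_cohort(
    cohort: list[tuple[RawRecording, str]], out_dir: str | Path
) -> Path:
    """Write per-channel logger files plus a cohort manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, label in cohort:
        paths = write_recording(rec, out_dir / rec.subject_id)
        row = {"subject_id": rec.subject_id, "label": label, "seed": rec.metadata.get("seed")}
        for name, path in paths.items():
            row[f"path_{name}"] = str(path.relative_to(out_dir))
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
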