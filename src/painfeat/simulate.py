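"""Synthetic heat-pain study simulator.

Emulates two thermode-stimulation acquisition protocols so the whole
comparison pipeline can run without access to any gated dataset:

* **PMDB scheme** — continuous recording; per subject, each of the five
  non-baseline temperature levels (NP, P1..P4) is applied 8 times for 10 s
  with randomised 20–30 s rests in between, and a continuous 0–100 CoVAS
  rating channel is recorded alongside the EDA and temperature traces.
* **BVDB scheme** — each of the five levels (T0..T4, T0 being the 32 °C
  baseline) is applied 20 times for 4 s with randomised 8–12 s pauses.

Per-subject calibration yields a pain threshold TP and pain tolerance TT;
levels are derived from the range R = (TT − TP)/4:
``Pi = TP + i·R`` (so P4 = TT) and ``NP = TP − R`` for the PMDB scheme,
``Ti = TP + (i − 1)·R`` for the BVDB scheme, with 32 °C baselines.

The electrodermal signal is modelled as a slowly drifting tonic level plus
stimulus-evoked skin conductance responses (bi-exponential kernels, ~1 s
rise, several-second recovery) whose amplitude grows with the painful level
index, decays multiplicatively with repetition (habituation) and is jittered
per event, plus sparse spontaneous (non-specific) responses and Gaussian
sensor noise.  The CoVAS trace is driven by the *same* per-event response
magnitudes, so subjective labels and physiology are coupled the way they are
in a real rating experiment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

PMDB = "pmdb"
BVDB = "bvdb"

BASELINE_TEMP = 32.0
PMDB_STIM_LEVELS = ("NP", "P1", "P2", "P3", "P4")
BVDB_STIM_LEVELS = ("T0", "T1", "T2", "T3", "T4")
PMDB_STIM_DURATION_S = 10.0
BVDB_STIM_DURATION_S = 4.0
PMDB_GAP_RANGE_S = (20.0, 30.0)
BVDB_GAP_RANGE_S = (8.0, 12.0)
PMDB_DEFAULT_REPETITIONS = 8
BVDB_DEFAULT_REPETITIONS = 20

# painful intensity weight per level: 0 for baselines and the non-painful
# stimulus, linearly increasing over the four painful levels
LEVEL_WEIGHT = {
    "B": 0.0, "NP": 0.0, "T0": 0.0,
    "P1": 0.25, "P2": 0.5, "P3": 0.75, "P4": 1.0,
    "T1": 0.25, "T2": 0.5, "T3": 0.75, "T4": 1.0,
}

# SCR kernel time constants (seconds): ~1.2 s rise to peak, ~4-8 s recovery
SCR_RISE_TAU_S = 0.75
SCR_DECAY_TAU_S = 3.0
SCR_KERNEL_LEN_S = 20.0

COVAS_LAG_S = 1.0       # reaction time before the rating starts to move
COVAS_RISE_S = 2.0      # ramp-up time of the slider
COVAS_FALL_S = 2.0      # return-to-zero time after stimulus offset
TEMP_RAMP_RATE = 10.0   # thermode ramp speed, °C/s


class CalibrationError(ValueError):
    """Raised when pain thresholds are inconsistent (TT <= TP, non-finite)."""


@dataclass
class EffectPreset:
    """Population-level effect-size parameters of the simulator.

    ``default`` approximates a realistic, noisy study; ``clean`` is a strong,
    low-noise effect used for recovery checks.  Units: conductance values are
    in microsiemens-like arbitrary units.
    """

    scr_gain: float = 0.5               # mean evoked amplitude at the top level
    scr_gain_subject_sd: float = 0.2    # log-scale between-subject spread
    amp_jitter_sd: float = 0.4          # log-scale within-subject event jitter
    noise_sd: float = 0.03              # additive sensor noise
    habituation_rate: float = 0.97      # per-repetition amplitude decay
    spontaneous_rate_per_min: float = 2.0
    drift_amplitude: float = 0.3        # tonic slow-drift amplitude
    covas_gain: float = 1.0             # rating per unit of response drive
    covas_jitter_sd: float = 0.1        # extra rating-specific log jitter


PRESETS = {
    "default": EffectPreset(),
    "clean": EffectPreset(scr_gain=1.0, scr_gain_subject_sd=0.1,
                          amp_jitter_sd=0.15, noise_sd=0.02,
                          habituation_rate=0.99, spontaneous_rate_per_min=1.0,
                          drift_amplitude=0.2, covas_jitter_sd=0.05),
}


@dataclass
class SubjectProfile:
    """Calibration thresholds and response parameters of one subject."""

    subject_id: str
    TP: float                      # pain threshold, °C
    TT: float                      # pain tolerance threshold, °C
    scr_gain: float = 0.5          # evoked amplitude scale (signal units)
    scr_latency: float = 1.5       # stimulus onset -> response onset, s
    habituation_rate: float = 0.97
    tonic_level: float = 5.0       # baseline conductance level
    noise_sd: float = 0.03
    rng_seed: int = 0
    amp_jitter_sd: float = 0.4
    spontaneous_rate_per_min: float = 2.0
    drift_amplitude: float = 0.3
    covas_gain: float = 1.0
    covas_jitter_sd: float = 0.1

    def __post_init__(self):
        if not (np.isfinite(self.TP) and np.isfinite(self.TT)):
            raise CalibrationError("thresholds must be finite")
        if not (BASELINE_TEMP < self.TP < self.TT):
            raise CalibrationError(
                f"need 32 < TP < TT, got TP={self.TP}, TT={self.TT}")
        if self.TT > 50.0:
            raise CalibrationError("pain tolerance above the 50 degC ceiling")
        if self.scr_gain < 0 or self.noise_sd < 0:
            raise ValueError("scr_gain and noise_sd must be non-negative")
        if not (0.0 < self.habituation_rate <= 1.0):
            raise ValueError("habituation_rate must lie in (0, 1]")


@dataclass
class StimulusEvent:
    """One thermode stimulus."""

    onset_s: float
    duration_s: float
    temperature: float
    level: str
    repetition_index: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.onset_s < 0:
            raise ValueError("invalid event timing")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Channel:
    fs: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class Recording:
    """One subject's continuous multichannel recording."""

    subject_id: str
    channels: dict
    temperature: Channel
    events: list
    duration_s: float
    covas: Optional[Channel] = None
    profile: Optional[SubjectProfile] = None
    scheme: str = PMDB


def stimulus_levels(TP: float, TT: float, scheme: str) -> dict:
    """Map level codes to temperatures for one calibrated subject.

    PMDB: B=32, NP=TP−R, Pi=TP+i·R (P4=TT); BVDB: T0=32, Ti=TP+(i−1)·R,
    with R=(TT−TP)/4 in both schemes.
    """
    if not (np.isfinite(TP) and np.isfinite(TT)):
        raise CalibrationError("thresholds must be finite")
    if TT <= TP:
        raise CalibrationError(f"need TT > TP, got TP={TP}, TT={TT}")
    r = (TT - TP) / 4.0
    if scheme == PMDB:
        levels = {"B": BASELINE_TEMP, "NP": TP - r}
        for i in range(1, 5):
            levels[f"P{i}"] = TP + i * r
    elif scheme == BVDB:
        levels = {"T0": BASELINE_TEMP}
        for i in range(1, 5):
            levels[f"T{i}"] = TP + (i - 1) * r
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return levels


def build_protocol(profile: SubjectProfile, scheme: str,
                   repetitions: Optional[int] = None, rng=None) -> list:
    """Randomised stimulation sequence for one subject.

    PMDB: each of NP/P1..P4 ``repetitions`` (default 8) times, 10-s stimuli,
    rests uniform in [20, 30] s.  BVDB: each of T0..T4 ``repetitions``
    (default 20) times, 4-s stimuli, pauses uniform in [8, 12] s.
    """
    rng = np.random.default_rng(profile.rng_seed) if rng is None else rng
    if scheme == PMDB:
        stim_levels = PMDB_STIM_LEVELS
        duration = PMDB_STIM_DURATION_S
        gap_lo, gap_hi = PMDB_GAP_RANGE_S
        repetitions = PMDB_DEFAULT_REPETITIONS if repetitions is None else repetitions
    elif scheme == BVDB:
        stim_levels = BVDB_STIM_LEVELS
        duration = BVDB_STIM_DURATION_S
        gap_lo, gap_hi = BVDB_GAP_RANGE_S
        repetitions = BVDB_DEFAULT_REPETITIONS if repetitions is None else repetitions
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")

    temps = stimulus_levels(profile.TP, profile.TT, scheme)
    order = [lv for lv in stim_levels for _ in range(repetitions)]
    rng.shuffle(order)
    events = []
    rep_count = {lv: 0 for lv in stim_levels}
    t = float(rng.uniform(gap_lo, gap_hi))
    for lv in order:
        events.append(StimulusEvent(onset_s=t, duration_s=duration,
                                    temperature=temps[lv], level=lv,
                                    repetition_index=rep_count[lv]))
        rep_count[lv] += 1
        t += duration + float(rng.uniform(gap_lo, gap_hi))
    return events


def _scr_kernel(fs: float, dtype=float) -> np.ndarray:
    """Unit-peak bi-exponential SCR shape sampled at fs."""
    t = np.arange(0.0, SCR_KERNEL_LEN_S, 1.0 / fs, dtype=dtype)
    k = np.exp(-t / SCR_DECAY_TAU_S) - np.exp(-t / SCR_RISE_TAU_S)
    return k / k.max()


def event_drives(profile: SubjectProfile, events: list, rng) -> np.ndarray:
    """Dimensionless per-event response drive shared by EDA and CoVAS.

    drive = level weight × habituation^repetition × log-normal jitter; zero
    for non-painful levels.  One random draw per event keeps the subjective
    rating coupled to the physiological response magnitude.
    """
    drives = np.zeros(len(events))
    for j, ev in enumerate(events):
        w = LEVEL_WEIGHT[ev.level]
        if w > 0:
            jitter = math.exp(rng.normal(0.0, profile.amp_jitter_sd))
            drives[j] = w * profile.habituation_rate ** ev.repetition_index * jitter
    return drives


def generate_eda(profile: SubjectProfile, events: list, fs: float,
                 duration_s: float, rng=None, drives=None,
                 return_components: bool = False):
    """Synthesise the EDA channel: tonic drift + evoked SCRs + noise.

    Evoked amplitude per event is ``scr_gain * drive`` delayed by the
    subject's response latency; the signal is clipped to be non-negative.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if events and max(ev.offset_s for ev in events) > duration_s:
        raise ValueError("events extend past the recording duration")
    rng = np.random.default_rng(profile.rng_seed + 1) if rng is None else rng
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # tonic: level + slow drift (spectral content well below 0.05 Hz)
    tonic = np.full(n, profile.tonic_level)
    if profile.drift_amplitude > 0:
        for _ in range(3):
            f0 = rng.uniform(0.002, 0.02)
            phase = rng.uniform(0, 2 * np.pi)
            tonic = tonic + (profile.drift_amplitude / 3.0) * np.sin(
                2 * np.pi * f0 * t + phase)

    if drives is None:
        drives = event_drives(profile, events, rng)
    kernel = _scr_kernel(fs)
    phasic = np.zeros(n)
    for ev, d in zip(events, drives):
        if d <= 0:
            continue
        start = int(round((ev.onset_s + profile.scr_latency) * fs))
        if start >= n:
            continue
        seg = kernel[: n - start]
        phasic[start: start + seg.size] += profile.scr_gain * d * seg

    # spontaneous (non-specific) SCRs
    rate = profile.spontaneous_rate_per_min / 60.0
    if rate > 0:
        n_spont = rng.poisson(rate * duration_s)
        for _ in range(n_spont):
            start = int(rng.uniform(0, n))
            amp = profile.scr_gain * rng.uniform(0.05, 0.3)
            seg = kernel[: n - start]
            phasic[start: start + seg.size] += amp * seg

    noise = rng.normal(0.0, profile.noise_sd, size=n) if profile.noise_sd > 0 else 0.0
    signal = np.clip(tonic + phasic + noise, 0.0, None)
    if return_components:
        return signal, tonic, phasic
    return signal


def generate_covas(profile: SubjectProfile, events: list, fs: float,
                   duration_s: float, rng=None, drives=None) -> np.ndarray:
    """Continuous 0-100 rating trace: zero outside painful stimuli, ramping
    to a plateau proportional to the event's perceived intensity."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if events and max(ev.offset_s for ev in events) > duration_s:
        raise ValueError("events extend past the recording duration")
    rng = np.random.default_rng(profile.rng_seed + 2) if rng is None else rng
    if drives is None:
        drives = event_drives(profile, events, rng)
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    t = np.arange(n) / fs
    for ev, d in zip(events, drives):
        if d <= 0:
            continue
        jitter = math.exp(rng.normal(0.0, profile.covas_jitter_sd))
        plateau = 100.0 * min(1.0, profile.covas_gain * d * jitter)
        start = ev.onset_s + COVAS_LAG_S
        hold_end = ev.offset_s
        fall_end = hold_end + COVAS_FALL_S
        m = (t >= start) & (t < fall_end)
        tt = t[m]
        ramp = np.clip((tt - start) / COVAS_RISE_S, 0.0, 1.0)
        fall = np.clip((fall_end - tt) / COVAS_FALL_S, 0.0, 1.0)
        trace[m] = np.maximum(trace[m], plateau * np.minimum(ramp, fall))
    return np.clip(trace, 0.0, 100.0)


def generate_temperature(events: list, fs: float, duration_s: float) -> np.ndarray:
    """Thermode temperature trace: 32 °C baseline with trapezoidal stimuli."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    trace = np.full(n, BASELINE_TEMP)
    for ev in events:
        rise = max(ev.temperature - BASELINE_TEMP, 0.0) / TEMP_RAMP_RATE
        m = (t >= ev.onset_s) & (t < ev.offset_s + rise)
        tt = t[m]
        up = np.clip((tt - ev.onset_s) / max(rise, 1e-9), 0.0, 1.0)
        down = np.clip((ev.offset_s + rise - tt) / max(rise, 1e-9), 0.0, 1.0)
        level = BASELINE_TEMP + (ev.temperature - BASELINE_TEMP) * np.minimum(up, down)
        trace[m] = np.maximum(trace[m], level)
    return trace


def generate_recording(profile: SubjectProfile, scheme: str = PMDB,
                       repetitions: Optional[int] = None,
                       fs: float = 256.0) -> Recording:
    """Full synthetic recording for one subject (EDA + temperature and, for
    the PMDB scheme, CoVAS), with all randomness derived from the profile's
    seed."""
    rng = np.random.default_rng(profile.rng_seed)
    events = build_protocol(profile, scheme, repetitions, rng)
    tail = PMDB_GAP_RANGE_S[1] if scheme == PMDB else BVDB_GAP_RANGE_S[1]
    duration_s = events[-1].offset_s + tail
    drives = event_drives(profile, events, rng)
    eda = generate_eda(profile, events, fs, duration_s, rng=rng, drives=drives)
    temp = generate_temperature(events, fs, duration_s)
    covas = None
    if scheme == PMDB:
        covas = Channel(fs, generate_covas(profile, events, fs, duration_s,
                                           rng=rng, drives=drives))
    return Recording(subject_id=profile.subject_id,
                     channels={"eda": Channel(fs, eda)},
                     temperature=Channel(fs, temp), events=events,
                     duration_s=duration_s, covas=covas, profile=profile,
                     scheme=scheme)


def sample_profile(subject_id: str, seed: int, preset: EffectPreset,
                   rng) -> SubjectProfile:
    """Draw one subject's calibration and response parameters."""
    tp = float(rng.uniform(40.0, 46.0))
    tt = min(tp + float(rng.uniform(2.0, 4.0)), 49.0)
    gain = preset.scr_gain * math.exp(rng.normal(0.0, preset.scr_gain_subject_sd))
    return SubjectProfile(
        subject_id=subject_id, TP=tp, TT=tt, scr_gain=gain,
        scr_latency=float(rng.uniform(1.0, 2.5)),
        habituation_rate=preset.habituation_rate,
        tonic_level=float(rng.uniform(2.0, 10.0)),
        noise_sd=preset.noise_sd, rng_seed=seed,
        amp_jitter_sd=preset.amp_jitter_sd,
        spontaneous_rate_per_min=preset.spontaneous_rate_per_min,
        drift_amplitude=preset.drift_amplitude,
        covas_gain=preset.covas_gain,
        covas_jitter_sd=preset.covas_jitter_sd)


def generate_dataset(n_subjects: int, scheme: str = PMDB,
                     repetitions: Optional[int] = None, fs: float = 256.0,
                     master_seed: int = 0, preset="default") -> list:
    """Reproducible multi-subject dataset: same master seed, same bytes."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if isinstance(preset, str):
        preset = PRESETS[preset]
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    recordings = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        profile = sample_profile(f"S{i + 1:03d}", seed, preset, rng)
        recordings.append(generate_recording(profile, scheme, repetitions, fs))
    return recordings


# ---------------------------------------------------------------------------
# on-disk format: one CSV per channel + a JSON manifest per subject

def save_recording(rec: Recording, outdir) -> Path:
    outdir = Path(outdir) / rec.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    named = dict(rec.channels)
    named["temperature"] = rec.temperature
    if rec.covas is not None:
        named["covas"] = rec.covas
    for name, ch in named.items():
        t = np.arange(ch.values.size) / ch.fs
        arr = np.column_stack([t, ch.values])
        np.savetxt(outdir / f"{name}.csv", arr, delimiter=",",
                   header="time_s,value", comments="", fmt="%.6f")
    manifest = {
        "subject_id": rec.subject_id,
        "scheme": rec.scheme,
        "duration_s": rec.duration_s,
        "channels": {name: ch.fs for name, ch in named.items()},
        "profile": asdict(rec.profile) if rec.profile else None,
        "events": [asdict(ev) for ev in rec.events],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def load_recording(subject_dir) -> Recording:
    subject_dir = Path(subject_dir)
    manifest = json.loads((subject_dir / "manifest.json").read_text())
    channels = {}
    for name, fs in manifest["channels"].items():
        arr = np.loadtxt(subject_dir / f"{name}.csv", delimiter=",", skiprows=1)
        channels[name] = Channel(fs, arr[:, 1])
    events = [StimulusEvent(**ev) for ev in manifest["events"]]
    profile = (SubjectProfile(**manifest["profile"])
               if manifest.get("profile") else None)
    return Recording(subject_id=manifest["subject_id"],
                     channels={k: v for k, v in channels.items()
                               if k not in ("temperature", "covas")},
                     temperature=channels["temperature"],
                     events=events, duration_s=manifest["duration_s"],
                     covas=channels.get("covas"), profile=profile,
                     scheme=manifest["scheme"])


def save_dataset(recordings, outdir):
    outdir = Path(outdir)
    for rec in recordings:
        save_recording(rec, outdir)
    return outdir


def load_dataset(dataset_dir) -> list:
    dataset_dir = Path(dataset_dir)
    dirs = sorted(d for d in dataset_dir.iterdir()
                  if (d / "manifest.json").exists())
    return [load_recording(d) for d in dirs]
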