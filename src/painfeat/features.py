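"""Tonic/phasic EDA decomposition, SCR event detection and the 38-dimensional
hand-crafted feature vector.

The decomposition applies a zero-phase (forward-backward) second-order
Butterworth filter with a 0.05 Hz cutoff in cascaded second-order sections:
the low-pass output is the tonic skin conductance level, the matching
high-pass output the phasic component.  Skin conductance responses are
detected on the phasic trace with an onset threshold of 0.01 and a minimum
peak amplitude of 0.05 (normalised per-window units): an event opens where
the trace rises through the onset threshold, peaks at the subsequent
maximum, and closes where the trace falls back through its onset value; the
half-recovery point is the first sample after the peak below
onset + amplitude/2.

Feature extractors are registered by name so external extractors can plug in
under the same contract; ``hcf_combined`` concatenates every registered
extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .preprocess import minmax_normalize

CUTOFF_HZ = 0.05
ONSET_THRESHOLD = 0.01
AMPLITUDE_THRESHOLD = 0.05


@dataclass
class DecompositionResult:
    tonic: np.ndarray
    phasic: np.ndarray
    fs: float


@dataclass
class SCREvent:
    """One detected skin conductance response."""

    onset_idx: int
    peak_idx: int
    offset_idx: int
    amplitude: float
    rise_time_s: float
    half_recovery_idx: Optional[int] = None
    half_recovery_time_s: Optional[float] = None


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def _sos(fs: float, btype: str):
    return butter(2, CUTOFF_HZ, btype=btype, fs=fs, output="sos")


def decompose(eda, fs: float, cutoff_hz: float = CUTOFF_HZ) -> DecompositionResult:
    """Zero-phase Butterworth split into tonic (low-pass) and phasic
    (high-pass) components."""
    eda = np.asarray(eda, dtype=float)
    if fs <= 0.1:
        raise ValueError("sampling rate too low for a 0.05 Hz cutoff")
    sos_lo = butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos_lo.shape[0] + 1)
    if eda.size <= padlen:
        raise ValueError(f"input too short for filtering (need > {padlen} samples)")
    tonic = sosfiltfilt(sos_lo, eda)
    sos_hi = butter(2, cutoff_hz, btype="highpass", fs=fs, output="sos")
    phasic = sosfiltfilt(sos_hi, eda)
    return DecompositionResult(tonic=tonic, phasic=phasic, fs=fs)


def detect_scrs(phasic, fs: float, onset_threshold: float = ONSET_THRESHOLD,
                amplitude_threshold: float = AMPLITUDE_THRESHOLD) -> list:
    """Threshold-based SCR detection on a phasic trace."""
    phasic = np.asarray(phasic, dtype=float)
    n = phasic.size
    events = []
    i = 1
    while i < n:
        if phasic[i - 1] < onset_threshold <= phasic[i]:
            onset = i
            onset_val = phasic[onset]
            j = onset + 1
            while j < n and phasic[j] >= onset_val:
                j += 1
            offset = min(j, n - 1)
            peak = onset + int(np.argmax(phasic[onset: offset + 1]))
            amplitude = float(phasic[peak] - onset_val)
            if peak > onset and amplitude >= amplitude_threshold:
                half_idx = None
                half_time = None
                half_level = onset_val + amplitude / 2.0
                below = np.nonzero(phasic[peak + 1:] < half_level)[0]
                if below.size:
                    half_idx = peak + 1 + int(below[0])
                    half_time = (half_idx - peak) / fs
                events.append(SCREvent(onset_idx=onset, peak_idx=peak,
                                       offset_idx=offset, amplitude=amplitude,
                                       rise_time_s=(peak - onset) / fs,
                                       half_recovery_idx=half_idx,
                                       half_recovery_time_s=half_time))
            i = offset + 1
        else:
            i += 1
    return events


def _mean_std(values) -> tuple:
    if len(values) == 0:
        return 0.0, 0.0
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std())


def _local_extrema(x: np.ndarray):
    """Strict 3-point local maxima/minima; a plateau contributes its first
    sample."""
    maxima = [x[i] for i in range(1, x.size - 1)
              if x[i - 1] < x[i] >= x[i + 1]]
    minima = [x[i] for i in range(1, x.size - 1)
              if x[i - 1] > x[i] <= x[i + 1]]
    return maxima, minima


def _cv(arr: np.ndarray) -> float:
    m = arr.mean()
    return float(arr.std() / abs(m)) if m != 0 else 0.0


HCF_FEATURE_NAMES = (
    "rms", "mean_local_max", "mean_local_min", "mav",
    "mavfd", "mavfd_std_signal", "mavsd", "mavsd_std_signal",
    "cv_moment1", "cv_moment2", "argmin_idx", "argmax_idx", "last_minus_first",
    "phasic_mean", "phasic_std", "tonic_mean", "tonic_std",
    "scr_amp_mean", "scr_amp_std", "scr_rise_mean", "scr_rise_std",
    "scr_half_rec_mean", "scr_half_rec_std",
    "tonic_recovery_mean", "tonic_recovery_std",
    "n_scrs", "scr_amp_sum", "first_scr_amp", "phasic_max",
    "norm_mean", "norm_std", "norm_var",
    "win_max", "win_min", "win_median", "win_iqr", "win_slope", "win_auc",
)


def extract_hcf(window, fs: float) -> FeatureVector:
    """The 38 hand-crafted EDA features of a single normalised window.

    Statistics over detected SCRs are zero when no SCR is present; the
    half-recovery statistics cover only events whose half-recovery point
    falls inside the window.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError("hand-crafted features expect a single channel")
        x = x[:, 0]
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")

    std = x.std()
    standardized = (x - x.mean()) / std if std > 0 else np.zeros_like(x)
    normalized = minmax_normalize(x)
    dec = decompose(x, fs)
    scrs = detect_scrs(dec.phasic, fs)

    maxima, minima = _local_extrema(x)
    fd = np.diff(x)
    sd = np.diff(x, n=2)
    fd_std = np.diff(standardized)
    sd_std = np.diff(standardized, n=2)

    amps = [e.amplitude for e in scrs]
    rises = [e.rise_time_s for e in scrs]
    halves = [e.half_recovery_time_s for e in scrs
              if e.half_recovery_time_s is not None]
    recov = [float(dec.tonic[e.offset_idx] - dec.tonic[e.onset_idx])
             for e in scrs]

    amp_mean, amp_std = _mean_std(amps)
    rise_mean, rise_std = _mean_std(rises)
    half_mean, half_std = _mean_std(halves)
    rec_mean, rec_std = _mean_std(recov)

    t = np.arange(x.size) / fs
    slope = float(np.polyfit(t, x, 1)[0]) if x.size > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])

    values = np.array([
        np.sqrt(np.mean(x ** 2)),
        np.mean(maxima) if maxima else 0.0,
        np.mean(minima) if minima else 0.0,
        np.mean(np.abs(x)),
        np.mean(np.abs(fd)) if fd.size else 0.0,
        np.mean(np.abs(fd_std)) if fd_std.size else 0.0,
        np.mean(np.abs(sd)) if sd.size else 0.0,
        np.mean(np.abs(sd_std)) if sd_std.size else 0.0,
        _cv(x),
        _cv(x ** 2),
        float(np.argmin(x)),
        float(np.argmax(x)),
        float(x[-1] - x[0]),
        float(dec.phasic.mean()), float(dec.phasic.std()),
        float(dec.tonic.mean()), float(dec.tonic.std()),
        amp_mean, amp_std, rise_mean, rise_std, half_mean, half_std,
        rec_mean, rec_std,
        float(len(scrs)),
        float(np.sum(amps)) if amps else 0.0,
        float(amps[0]) if amps else 0.0,
        float(dec.phasic.max()),
        float(normalized.mean()), float(normalized.std()),
        float(normalized.var()),
        float(x.max()), float(x.min()), float(np.median(x)),
        float(q75 - q25), slope,
        float(np.trapezoid(x, dx=1.0 / fs)),
    ])
    return FeatureVector(values=values, names=HCF_FEATURE_NAMES)


# ---------------------------------------------------------------------------
# extractor registry

FEATURE_EXTRACTORS: dict = {}


def register_extractor(name: str):
    """Register a window-level feature extractor under ``name``.

    An extractor is ``f(window, fs) -> FeatureVector``; ``hcf_combined``
    concatenates all registered extractors in registration order."""
    def deco(fn: Callable):
        FEATURE_EXTRACTORS[name] = fn
        return fn
    return deco


register_extractor("hcf")(extract_hcf)


def extract_combined(window, fs: float) -> FeatureVector:
    values, names = [], []
    for name, fn in FEATURE_EXTRACTORS.items():
        fv = fn(window, fs)
        values.append(fv.values)
        names.extend(f"{name}.{n}" for n in fv.names)
    return FeatureVector(values=np.concatenate(values), names=tuple(names))


def feature_matrix(segments, method: str = "hcf") -> pd.DataFrame:
    """Window-level feature table with subject ids and labels attached."""
    if method == "hcf_combined":
        fn = extract_combined
    else:
        try:
            fn = FEATURE_EXTRACTORS[method]
        except KeyError:
            raise KeyError(f"unregistered feature extractor {method!r}") from None
    rows, names = [], None
    for seg in segments:
        fv = fn(seg.data, seg.fs)
        names = fv.names
        rows.append(fv.values)
    df = pd.DataFrame(np.asarray(rows), columns=list(names))
    df.insert(0, "subject_id", [s.subject_id for s in segments])
    df.insert(1, "temp_label", [s.temp_label for s in segments])
    df.insert(2, "covas_label", [s.covas_label for s in segments])
    df.insert(3, "covas_sum", [s.covas_sum for s in segments])
    return df
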