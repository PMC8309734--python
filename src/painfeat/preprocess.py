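"""Resampling, stimulus-aligned windowing, per-window normalisation and
label construction.

All channels are brought to a common 256 Hz grid by linear interpolation.
Window geometry follows the two acquisition schemes:

* PMDB — one 10-s window per stimulus starting at its onset (2560 samples at
  256 Hz), labelled with the stimulus level, plus the 10-s window preceding
  each onset labelled with the no-stimulus baseline class ``B``.
* BVDB — one 5.5-s window per stimulus starting 3 s after its onset
  (1408 samples at 256 Hz); the 32 °C ``T0`` stimuli provide the baseline
  class.

Each window is min-max normalised per channel to [0, 1].  Subjective labels
C0..C4 are built per subject by summing the CoVAS trace inside each window,
scaling by the subject's maximum window sum, and binning the scaled value
into 0 → C0, ]0,0.25] → C1, ]0.25,0.5] → C2, ]0.5,0.75] → C3, ]0.75,1] → C4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulate import PMDB, BVDB, Recording, StimulusEvent, Channel

logger = logging.getLogger(__name__)

COMMON_FS = 256.0
PMDB_WINDOW_S = 10.0
BVDB_WINDOW_S = 5.5
BVDB_WINDOW_DELAY_S = 3.0
COVAS_BIN_EDGES = (0.25, 0.5, 0.75)


@dataclass
class Segment:
    """One fixed-length stimulus-aligned window of sensor data."""

    subject_id: str
    data: np.ndarray          # (T, S) after normalisation, entries in [0, 1]
    fs: float
    temp_label: str
    start_idx: int            # start sample on the common-rate grid
    source_event: Optional[StimulusEvent] = None
    covas_label: Optional[str] = None
    covas_sum: Optional[float] = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def resample_channel(values, fs_in: float, fs_out: float = COMMON_FS) -> np.ndarray:
    """Linear-interpolation resampling onto the uniform fs_out grid spanning
    the input's time range."""
    values = np.asarray(values, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if values.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if fs_in == fs_out:
        return values.copy()
    n_out = int(np.floor((values.size - 1) / fs_in * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    t_in = np.arange(values.size) / fs_in
    return np.interp(t_out, t_in, values)


def minmax_normalize(window) -> np.ndarray:
    """Per-channel (x − min)/(max − min) onto [0, 1]; constant channels map
    to all-zeros."""
    x = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    out = np.zeros_like(x)
    nz = span > 0
    out[:, nz] = (x[:, nz] - lo[nz]) / span[nz]
    return out[:, 0] if squeeze else out


def resample_recording(rec: Recording, fs_out: float = COMMON_FS) -> Recording:
    """All channels (sensors, temperature, CoVAS) onto the common grid."""
    channels = {name: Channel(fs_out, resample_channel(ch.values, ch.fs, fs_out))
                for name, ch in rec.channels.items()}
    temp = Channel(fs_out, resample_channel(rec.temperature.values,
                                            rec.temperature.fs, fs_out))
    covas = None
    if rec.covas is not None:
        covas = Channel(fs_out, resample_channel(rec.covas.values,
                                                 rec.covas.fs, fs_out))
    return Recording(subject_id=rec.subject_id, channels=channels,
                     temperature=temp, events=rec.events,
                     duration_s=rec.duration_s, covas=covas,
                     profile=rec.profile, scheme=rec.scheme)


def _cut(data: np.ndarray, start_idx: int, n: int):
    if start_idx < 0 or start_idx + n > data.shape[0]:
        return None
    return data[start_idx: start_idx + n]


def segment_recording(rec: Recording, scheme: Optional[str] = None,
                      channels=("eda",), fs: float = COMMON_FS,
                      normalize: bool = True) -> list:
    """Cut stimulus-aligned windows out of a recording.

    The recording is resampled to ``fs`` first.  Windows that would extend
    outside the recording are dropped with a warning.  Returned segments
    carry the objective temperature label; CoVAS labels are attached
    separately by :func:`covas_labels`.
    """
    scheme = rec.scheme if scheme is None else scheme
    rec = resample_recording(rec, fs)
    data = np.column_stack([rec.channels[name].values for name in channels])
    segments = []
    if scheme == PMDB:
        n = int(round(PMDB_WINDOW_S * fs))
        for ev in rec.events:
            onset_idx = int(round(ev.onset_s * fs))
            stim = _cut(data, onset_idx, n)
            if stim is None:
                logger.warning("dropping out-of-range stimulus window at %.1f s "
                               "(subject %s)", ev.onset_s, rec.subject_id)
            else:
                segments.append(Segment(rec.subject_id,
                                        minmax_normalize(stim) if normalize else stim,
                                        fs, ev.level, onset_idx, ev))
            base = _cut(data, onset_idx - n, n)
            if base is None:
                logger.warning("dropping out-of-range baseline window before "
                               "%.1f s (subject %s)", ev.onset_s, rec.subject_id)
            else:
                segments.append(Segment(rec.subject_id,
                                        minmax_normalize(base) if normalize else base,
                                        fs, "B", onset_idx - n, ev))
    elif scheme == BVDB:
        n = int(round(BVDB_WINDOW_S * fs))
        for ev in rec.events:
            start_idx = int(round((ev.onset_s + BVDB_WINDOW_DELAY_S) * fs))
            win = _cut(data, start_idx, n)
            if win is None:
                logger.warning("dropping out-of-range window at %.1f s "
                               "(subject %s)", ev.onset_s, rec.subject_id)
                continue
            segments.append(Segment(rec.subject_id,
                                    minmax_normalize(win) if normalize else win,
                                    fs, ev.level, start_idx, ev))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return segments


def covas_bin(scaled: float) -> str:
    """Fixed quartile binning of a per-subject-scaled CoVAS sum."""
    if scaled == 0:
        return "C0"
    idx = int(np.searchsorted(COVAS_BIN_EDGES, scaled, side="left")) + 1
    return f"C{idx}"


def covas_labels(segments: list, covas_values, fs: float = COMMON_FS) -> list:
    """Attach per-subject scaled CoVAS sums and C0..C4 labels in place.

    All segments must belong to one subject; ``covas_values`` is that
    subject's rating trace on the same common-rate clock the segments were
    cut on.
    """
    subjects = {s.subject_id for s in segments}
    if len(subjects) > 1:
        raise ValueError(f"segments from multiple subjects: {sorted(subjects)}")
    covas_values = np.asarray(covas_values, dtype=float)
    sums = []
    for seg in segments:
        window = covas_values[seg.start_idx: seg.start_idx + seg.n_samples]
        sums.append(float(window.sum()))
    max_sum = max(sums) if sums else 0.0
    for seg, s in zip(segments, sums):
        seg.covas_sum = s
        scaled = s / max_sum if max_sum > 0 else 0.0
        seg.covas_label = covas_bin(scaled)
    return segments


def segment_dataset(recordings, channels=("eda",), fs: float = COMMON_FS) -> list:
    """Segment every recording; PMDB recordings also get CoVAS labels."""
    all_segments = []
    for rec in recordings:
        segs = segment_recording(rec, channels=channels, fs=fs)
        if rec.covas is not None:
            trace = resample_channel(rec.covas.values, rec.covas.fs, fs)
            covas_labels(segs, trace, fs)
        all_segments.extend(segs)
    return all_segments


def segments_to_array(segments) -> np.ndarray:
    """Stack equally-shaped segments into an (n, T, S) array."""
    return np.stack([seg.data for seg in segments])
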