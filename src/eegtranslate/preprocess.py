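"""Filtering, referencing, normalization and segmentation of continuous
paired recordings.

The pipeline applied to concurrent recordings before training is: 1 Hz
high-pass and 50 Hz notch on both streams (zero-phase, to preserve spike
morphology), common average reference on the scalp stream only, per-recording
min-max normalization to [-1, 1], then windowing into 320 ms (64-sample)
segments spanning 160 ms before and after each IED onset, with an equal
number of non-IED windows drawn from onset-free stretches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .segment_store import IntracranialSegment, PairedSegment, ScalpSegment

__all__ = [
    "PreprocessConfig",
    "highpass",
    "notch",
    "common_average_reference",
    "normalize_minmax",
    "preprocess_recording",
    "extract_segments",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_cutoff: float = 1.0      # Hz
    notch_freq: float = 50.0          # Hz (power-line interference)
    segment_length: int = 64          # samples
    pre_onset: float = 0.160          # s before the IED onset
    post_onset: float = 0.160         # s from the onset onward
    apply_car_to_scalp: bool = True
    notch_quality: float = 30.0
    highpass_order: int = 4

    def window(self, rate: float) -> tuple[int, int]:
        """(samples before onset, samples from onset): [onset - pre, onset + post)."""
        pre = int(round(self.pre_onset * rate))
        post = int(round(self.post_onset * rate))
        if pre + post != self.segment_length:
            raise ValueError(
                f"pre_onset + post_onset at {rate} Hz gives {pre + post} samples, "
                f"but segment_length is {self.segment_length}"
            )
        return pre, post


def _check_signal(x, rate: float) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected (time, sensors) array, got shape {arr.shape}")
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    return arr


def highpass(x, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass along time; removes DC, keeps shape."""
    arr = _check_signal(x, rate)
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({rate / 2} Hz)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, arr, axis=0)


def notch(x, freq: float, rate: float, quality: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` (power-line removal)."""
    arr = _check_signal(x, rate)
    if freq >= rate / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist ({rate / 2} Hz)")
    b, a = signal.iirnotch(freq, quality, fs=rate)
    return signal.filtfilt(b, a, arr, axis=0)


def common_average_reference(scalp) -> np.ndarray:
    """Subtract the across-sensor mean at every time sample (scalp only)."""
    arr = np.asarray(scalp, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("common average reference needs at least 2 sensors")
    return arr - arr.mean(axis=1, keepdims=True)


def normalize_minmax(x) -> np.ndarray:
    """Per-recording min-max scaling to [-1, 1] (keeps zero if symmetric)."""
    arr = np.asarray(x, dtype=float)
    peak = np.abs(arr).max()
    return arr / peak if peak > 0 else arr.copy()


def preprocess_recording(scalp, intracranial, rate: float,
                         cfg: PreprocessConfig | None = None):
    """Full continuous-domain pipeline; returns (scalp, intracranial).

    Filters are applied to both streams; the common average reference only to
    the scalp; both streams are then min-max normalized per recording.
    """
    cfg = cfg or PreprocessConfig()
    out = []
    for stream, is_scalp in ((scalp, True), (intracranial, False)):
        arr = highpass(stream, cfg.highpass_cutoff, rate, cfg.highpass_order)
        arr = notch(arr, cfg.notch_freq, rate, cfg.notch_quality)
        if is_scalp and cfg.apply_car_to_scalp:
            arr = common_average_reference(arr)
        out.append(normalize_minmax(arr))
    return out[0], out[1]


def extract_segments(scalp, intracranial, rate: float, onsets,
                     cfg: PreprocessConfig | None = None,
                     seed: int = 0, subject_id: str = "subject") -> list[PairedSegment]:
    """Cut IED windows around each onset plus an equal number of seeded
    non-IED windows from onset-free stretches.

    Each IED window is ``[onset - pre, onset + post)`` (32 + 32 samples at
    200 Hz).  Onsets too close to an edge are skipped with a warning.
    Non-IED windows never overlap any IED window.
    """
    cfg = cfg or PreprocessConfig()
    scalp = _check_signal(scalp, rate)
    intracranial = _check_signal(intracranial, rate)
    if scalp.shape[0] != intracranial.shape[0]:
        raise ValueError("scalp and intracranial streams differ in length")
    T = scalp.shape[0]
    pre, post = cfg.window(rate)
    L = cfg.segment_length

    ied_windows = []
    for onset in sorted(int(o) for o in onsets):
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > T:
            logger.warning("subject %s: onset %d too close to the recording edge; skipped",
                           subject_id, onset)
            continue
        ied_windows.append((lo, hi, onset))

    # candidate non-IED starts: windows [s, s+L) disjoint from every IED window
    blocked = np.zeros(T, dtype=bool)
    for lo, hi, _ in ied_windows:
        blocked[max(lo - L + 1, 0):hi] = True
    candidates = np.flatnonzero(~blocked[: T - L + 1])
    rng = np.random.default_rng(seed)
    k = len(ied_windows)
    if len(candidates) < k:
        raise ValueError(
            f"subject {subject_id}: only {len(candidates)} onset-free window positions "
            f"available for {k} non-IED segments"
        )
    starts = np.sort(rng.choice(candidates, size=k, replace=False))

    segments = []
    for lo, hi, onset in ied_windows:
        segments.append(PairedSegment(
            scalp=ScalpSegment(scalp[lo:hi], sampling_rate=rate, onset_index=pre),
            intracranial=IntracranialSegment(intracranial[lo:hi]),
            label="IED", subject_id=subject_id,
        ))
    for s in starts:
        segments.append(PairedSegment(
            scalp=ScalpSegment(scalp[s:s + L], sampling_rate=rate, onset_index=None),
            intracranial=IntracranialSegment(intracranial[s:s + L]),
            label="nonIED", subject_id=subject_id,
        ))
    return segments
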