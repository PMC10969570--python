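"""Envelope-based segmentation of lifting actions.

The lifting regions of interest (ROIs) are located on the x-axis (longitudinal)
acceleration channel in three steps:

1. 4th-order Butterworth band-pass, 1-50 Hz, applied forward-backward
   (zero phase) so ROI boundaries are not delayed; removes the DC/gravity
   component.
2. Full-wave rectification followed by Savitzky-Golay smoothing
   (polynomial order 4, frame length 1101 samples at 200 Hz, i.e. ~5.5 s),
   yielding a slowly varying amplitude envelope.
3. Intersection of the envelope with a per-trial threshold: each upward
   crossing opens an ROI, the next downward crossing closes it.  Runs
   shorter than ``min_duration`` are discarded and gaps shorter than
   ``min_gap`` merged, which guards against noise-induced double crossings.

The detected [start, stop) intervals are then cut from the *original*
(unfiltered) channels, so the features downstream see the raw waveform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .config import RunConfig
from .errors import ConfigError, DataError
from .synth import SixChannelSignal

__all__ = [
    "ROI",
    "Envelope",
    "bandpass",
    "rectify",
    "smooth",
    "detect_rois",
    "extract_rois",
    "compute_envelope",
    "segment_signal",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """Half-open sample interval [start, stop) of one lifting action."""

    start: int
    stop: int
    subject_id: int = -1
    lifting_index: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise DataError(f"invalid ROI bounds [{self.start}, {self.stop})")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class Envelope:
    """Non-negative amplitude envelope plus a record of how it was made."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigError("envelope must be one-dimensional")
        if (self.values < 0).any():
            raise DataError("envelope values must be non-negative")


# ----------------------------------------------------------------------
def bandpass(
    x: np.ndarray,
    sampling_rate: float,
    low: float = 1.0,
    high: float = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one channel.

    Forward-backward filtering doubles the effective order but keeps every
    sample aligned in time, which matters because the detected boundaries
    are transferred to the unfiltered channels.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if not (0 < low < high):
        raise ConfigError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ConfigError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, x)


def rectify(x: np.ndarray) -> Envelope:
    """Full-wave rectification (elementwise absolute value)."""
    return Envelope(values=np.abs(np.asarray(x, dtype=float)), provenance="rectified")


def smooth(env: Envelope, polyorder: int = 4, framelen: int = 1101) -> Envelope:
    """Savitzky-Golay smoothing of a rectified envelope.

    If ``framelen`` exceeds the signal length it is clipped to the largest
    valid odd value (logged); short test signals would otherwise be
    unprocessable.  Small negative undershoots of the least-squares fit are
    clamped to zero so the result remains a valid envelope.
    """
    if framelen % 2 == 0:
        raise ConfigError(f"framelen must be odd, got {framelen}")
    if framelen <= polyorder:
        raise ConfigError(f"framelen {framelen} must exceed polyorder {polyorder}")
    n = env.values.size
    if framelen > n:
        clipped = n if n % 2 == 1 else n - 1
        if clipped <= polyorder:
            raise ConfigError(f"signal of {n} samples too short for polyorder {polyorder}")
        log.warning("Savitzky-Golay framelen %d > signal length %d; clipped to %d",
                    framelen, n, clipped)
        framelen = clipped
    out = savgol_filter(env.values, framelen, polyorder)
    return Envelope(
        values=np.clip(out, 0.0, None),
        provenance=f"{env.provenance}|savgol(p={polyorder},w={framelen})",
    )


def detect_rois(
    env: Envelope,
    threshold: float,
    min_duration: int = 0,
    min_gap: int = 0,
    subject_id: int = -1,
) -> list[ROI]:
    """Threshold intersection: one ROI per contiguous supra-threshold run.

    A sample belongs to an ROI when ``env >= threshold`` (a tie counts as
    inside).  Gaps shorter than ``min_gap`` samples are merged first, then
    runs shorter than ``min_duration`` samples dropped.  An envelope that
    never reaches the threshold yields an empty list.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be positive, got {threshold}")
    above = env.values >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(env.values.size)

    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_duration]
    return [
        ROI(start=s, stop=e, subject_id=subject_id, lifting_index=i)
        for i, (s, e) in enumerate(kept)
    ]


def extract_rois(signal: SixChannelSignal, rois: list[ROI]) -> list[np.ndarray]:
    """Slice every ROI out of all six *original* channels.

    Segmentation ran on the filtered x-axis acceleration only; the cuts are
    applied to the raw matrix so downstream features see unfiltered data.
    """
    n = signal.n_samples
    out = []
    for roi in rois:
        if roi.stop > n:
            raise DataError(f"ROI [{roi.start}, {roi.stop}) exceeds signal length {n}")
        out.append(signal.samples[roi.start:roi.stop, :].copy())
    return out


# ----------------------------------------------------------------------
def compute_envelope(signal: SixChannelSignal, cfg: RunConfig) -> Envelope:
    """Filtered, rectified, smoothed envelope of the x-axis acceleration."""
    ax = signal.samples[:, 0]
    filtered = bandpass(
        ax, signal.sampling_rate, cfg.filter_band[0], cfg.filter_band[1], cfg.filter_order
    )
    return smooth(rectify(filtered), cfg.sg_polyorder, cfg.sg_framelen)


def resolve_threshold(env: Envelope, cfg: RunConfig) -> float:
    """Per-trial threshold: envelope quantile (default) or fixed value."""
    if cfg.threshold_mode == "fixed":
        return cfg.threshold_value
    return float(np.quantile(env.values, cfg.threshold_value))


def segment_signal(signal: SixChannelSignal, cfg: RunConfig) -> list[ROI]:
    """Full three-step segmentation of one trial."""
    env = compute_envelope(signal, cfg)
    thr = resolve_threshold(env, cfg)
    fs = signal.sampling_rate
    return detect_rois(
        env,
        thr,
        min_duration=int(round(cfg.min_duration_s * fs)),
        min_gap=int(round(cfg.min_gap_s * fs)),
        subject_id=signal.subject_id,
    )
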