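"""Core multichannel MCG signal handling.

Loading, filtering, beat detection and averaging, RMS reference computation
and automatic QRS / T-wave segmentation of multichannel magnetocardiographic
recordings acquired by a planar SQUID gradiometer array (64 channels at
500 Hz in the reference device).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

log = logging.getLogger(__name__)

__all__ = [
    "SensorGrid",
    "MultiChannelRecording",
    "AveragedBeat",
    "Segmentation",
    "SegmentationError",
    "InsufficientBeatsError",
    "detect_beats",
    "average_beats",
    "bandpass_filter",
    "filter_recording",
    "compute_rms_reference",
    "isoline_correct",
    "segment_beat",
    "heart_rate",
]


class InsufficientBeatsError(ValueError):
    """Raised when fewer than two heartbeats can be located in a recording."""


class SegmentationError(ValueError):
    """Raised when QRS / T-wave fiducials cannot be located on a beat."""


@dataclass(frozen=True)
class SensorGrid:
    """Planar sensor array geometry.

    Parameters
    ----------
    positions
        ``(N, 2)`` sensor coordinates in metres, one row per channel,
        ordered row-major to match the recording's channel columns.
    spacing
        Nominal inter-sensor spacing in metres.
    layout
        ``(rows, cols)`` of the rectangular array.
    """

    positions: np.ndarray
    spacing: float
    layout: tuple[int, int]

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if pos.shape[0] < 4:
            raise ValueError("a sensor grid needs at least 4 channels")
        # pairwise-distinct check via lexicographic sort
        order = np.lexsort(pos.T)
        if np.any(np.all(np.diff(pos[order], axis=0) == 0, axis=1)):
            raise ValueError("sensor positions must be pairwise distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def regular(cls, rows: int = 8, cols: int = 8, spacing: float = 0.04) -> "SensorGrid":
        """Centred regular rows x cols grid (default 8x8, 4 cm pitch)."""
        xs = (np.arange(cols) - (cols - 1) / 2.0) * spacing
        ys = (np.arange(rows) - (rows - 1) / 2.0) * spacing
        gx, gy = np.meshgrid(xs, ys)
        return cls(np.column_stack([gx.ravel(), gy.ravel()]), spacing, (rows, cols))


@dataclass
class MultiChannelRecording:
    """Raw or filtered multichannel recording.

    ``data`` is ``(samples, channels)`` in picotesla. ``channel_mask`` flags
    active channels; masked channels are excluded from every N-normalised
    quantity downstream.
    """

    data: np.ndarray
    fs: float
    grid: SensorGrid
    phase: str = "rest"
    channel_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (samples, channels)")
        if self.data.shape[1] != self.grid.n_channels:
            raise ValueError("channel count does not match grid")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.phase not in ("rest", "stress"):
            raise ValueError("phase must be 'rest' or 'stress'")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.shape != (self.data.shape[1],):
                raise ValueError("channel_mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class AveragedBeat:
    """One representative (arithmetically averaged) heartbeat per channel.

    ``rms`` is the cross-channel RMS reference signal R(t) recomputed over
    active channels; ``peak_index`` marks the registration point (R peak).
    """

    beat: np.ndarray
    rms: np.ndarray
    fs: float
    n_averaged: int
    grid: SensorGrid
    channel_mask: np.ndarray
    phase: str = "rest"
    peak_index: int = 0

    @property
    def n_samples(self) -> int:
        return self.beat.shape[0]


@dataclass(frozen=True)
class Segmentation:
    """Fiducial sample indices of one beat (0-based, closed intervals)."""

    qrs_beg: int
    qrs_end: int
    t_beg: int
    t_max: int
    t_end: int

    def __post_init__(self):
        if not (self.qrs_beg < self.qrs_end <= self.t_beg < self.t_max < self.t_end):
            raise ValueError(
                "fiducials must satisfy qrs_beg < qrs_end <= t_beg < t_max < t_end, "
                f"got {self}"
            )


def compute_rms_reference(beat: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Cross-channel RMS reference signal.

    R(t) = sqrt( (1/N) * sum_n B_n(t)^2 ) over the N active channels.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.ndim == 1:
        beat = beat[:, None]
    if mask is None:
        mask = np.ones(beat.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("at least one active channel is required")
    return np.sqrt(np.mean(beat[:, mask] ** 2, axis=1))


def _instantaneous_rms(rec: MultiChannelRecording) -> np.ndarray:
    # high-pass at 1 Hz to suppress baseline before peak picking
    sos = scipy.signal.butter(2, 1.0, "highpass", fs=rec.fs, output="sos")
    hp = scipy.signal.sosfiltfilt(sos, rec.data[:, rec.channel_mask], axis=0)
    return np.sqrt(np.mean(hp**2, axis=1))


def detect_beats(rec: MultiChannelRecording, refractory_s: float = 0.2) -> np.ndarray:
    """Locate R peaks on the instantaneous cross-channel RMS trace.

    Adaptive-threshold peak picking (threshold = 40% of the 98th percentile
    of the RMS trace) with a 200 ms refractory period.  Returns strictly
    increasing sample indices, one per QRS complex.
    """
    if rec.n_samples < 2 * rec.fs:
        raise InsufficientBeatsError("recording shorter than 2 s")
    trace = _instantaneous_rms(rec)
    top = np.percentile(trace, 98)
    if top <= 0:
        raise InsufficientBeatsError("no signal energy in recording")
    peaks, _ = scipy.signal.find_peaks(
        trace, height=0.4 * top, distance=max(1, int(round(refractory_s * rec.fs)))
    )
    if len(peaks) < 2:
        raise InsufficientBeatsError(f"only {len(peaks)} beat(s) detected")
    return peaks.astype(int)


def average_beats(
    rec: MultiChannelRecording,
    onsets: np.ndarray,
    window_s: tuple[float, float] = (-0.3, 0.6),
) -> AveragedBeat:
    """Register beats on the detected R peak and average them per channel.

    The default window spans 300 ms before to 600 ms after the peak; its end
    is clipped to the median inter-beat interval (minus a 120 ms guard) so
    that the next QRS never bleeds into the representative beat.  Beats whose
    window exceeds the recording bounds are dropped with a warning.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 2:
        raise InsufficientBeatsError("need at least 2 beats to average")
    ibi = float(np.median(np.diff(onsets)))
    pre = int(round(-window_s[0] * rec.fs))
    post = int(round(window_s[1] * rec.fs))
    post = min(post, int(ibi) - int(round(0.12 * rec.fs)))
    if post <= 0:
        raise ValueError("averaging window collapsed; inter-beat interval too short")
    windows = []
    dropped = 0
    for p in onsets:
        if p - pre < 0 or p + post > rec.n_samples:
            dropped += 1
            continue
        windows.append(rec.data[p - pre : p + post])
    if dropped:
        log.warning("dropped %d beat(s) whose window exceeded recording bounds", dropped)
    if not windows:
        raise InsufficientBeatsError("no beat window fits inside the recording")
    beat = np.mean(windows, axis=0)
    rms = compute_rms_reference(beat, rec.channel_mask)
    return AveragedBeat(
        beat=beat,
        rms=rms,
        fs=rec.fs,
        n_averaged=len(windows),
        grid=rec.grid,
        channel_mask=rec.channel_mask.copy(),
        phase=rec.phase,
        peak_index=pre,
    )


def isoline_correct(beat: AveragedBeat, guard_s: float = 0.12) -> AveragedBeat:
    """Re-reference each channel to its pre-QRS isoline.

    Band-pass filtering removes each channel's time average, which offsets
    the flat diastolic baseline away from zero by the beat's net
    time-integral.  Following the convention of taking the isoline at the
    beginning of the QRS complex, the per-channel mean over the window from
    the beat start to ``guard_s`` before the R peak is subtracted.
    """
    base_end = beat.peak_index - int(round(guard_s * beat.fs))
    if base_end < 1:
        raise ValueError("beat window has no pre-QRS baseline segment")
    data = beat.beat - beat.beat[:base_end].mean(axis=0)
    rms = compute_rms_reference(data, beat.channel_mask)
    return replace(beat, beat=data, rms=rms)


def _design_bandpass(low_hz: float, high_hz: float, fs: float, order: int):
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) Hz at fs={fs}")
    return scipy.signal.butter(order, [low_hz, high_hz], "bandpass", fs=fs, output="sos")


def bandpass_filter(
    beat: AveragedBeat,
    low_hz: float = 0.3,
    high_hz: float = 100.0,
    order: int = 4,
) -> AveragedBeat:
    """Zero-phase band-pass (default 0.3-100 Hz) plus linear detrend.

    Forward-backward Butterworth filtering per channel removes out-of-band
    content without phase distortion; a linear detrend removes residual
    baseline drift.  The RMS reference is recomputed afterwards.
    """
    sos = _design_bandpass(low_hz, high_hz, beat.fs, order)
    data = scipy.signal.detrend(beat.beat, axis=0, type="linear")
    # maximal padding: the low cut-off pole rings over seconds, far longer
    # than the default pad, and would otherwise leak into short beats
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = scipy.signal.sosfiltfilt(sos, data, axis=0, padlen=data.shape[0] - 1)
    rms = compute_rms_reference(data, beat.channel_mask)
    return replace(beat, beat=data, rms=rms)


def filter_recording(
    rec: MultiChannelRecording,
    low_hz: float = 0.3,
    high_hz: float = 100.0,
    order: int = 4,
) -> MultiChannelRecording:
    """Apply the standard zero-phase band-pass to a full raw recording."""
    sos = _design_bandpass(low_hz, high_hz, rec.fs, order)
    data = scipy.signal.detrend(rec.data, axis=0, type="linear")
    pad = min(rec.n_samples - 1, int(3 * rec.fs / low_hz))
    data = scipy.signal.sosfiltfilt(sos, data, axis=0, padlen=pad)
    return MultiChannelRecording(
        data=data, fs=rec.fs, grid=rec.grid, phase=rec.phase,
        channel_mask=rec.channel_mask.copy(),
    )


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    win = max(5, int(round(0.02 * fs)) | 1)  # ~20 ms, odd
    if len(x) <= win:
        return x
    return scipy.signal.savgol_filter(x, win, 3)


def _cross_down(r: np.ndarray, start: int, level: float) -> int | None:
    """First downward crossing of ``level`` at/after ``start``, interpolated."""
    below = np.flatnonzero(r[start:] < level)
    if len(below) == 0:
        return None
    k = start + int(below[0])
    if k == start or r[k - 1] == r[k]:
        return k
    frac = (r[k - 1] - level) / (r[k - 1] - r[k])
    return int(round(k - 1 + frac))


def _cross_up_back(r: np.ndarray, end: int, level: float) -> int:
    """Last sample at/below ``level`` before ``end``, interpolated."""
    below = np.flatnonzero(r[:end] <= level)
    if len(below) == 0:
        return 0
    k = int(below[-1])
    if k + 1 >= end or r[k + 1] == r[k]:
        return k
    frac = (level - r[k]) / (r[k + 1] - r[k])
    return int(round(k + frac))


def segment_beat(
    beat: AveragedBeat,
    isoline_fraction: float = 0.05,
    refractory_s: float = 0.08,
    t_search_s: float = 0.40,
) -> Segmentation:
    """Automatic QRS / T-wave segmentation on the RMS reference signal.

    The dominant R(t) lobe is taken as the QRS complex; ``qrs_beg`` /
    ``qrs_end`` are the (interpolated) crossings of ``isoline_fraction`` of
    the QRS peak on either side.  ``t_max`` is the R(t) argmax in a
    physiologic window after ``qrs_end``, ``t_beg`` the steepest upstroke of
    the lobe rising into the T peak, and ``t_end`` the return of R(t) below
    ``isoline_fraction`` of the T peak after ``t_max``.  The noise floor of
    R(t) (which adds to the signal in quadrature) is removed before
    thresholding, implementing the isoline convention.
    """
    rms = np.asarray(beat.rms, dtype=float)
    n = len(rms)
    if n < 20 or np.ptp(rms) == 0:
        raise SegmentationError("flat or too-short RMS trace")
    r = _smooth(rms, beat.fs)
    floor = np.percentile(r, 10)
    r = np.sqrt(np.clip(r**2 - floor**2, 0.0, None))
    # heavier smoothing for the low-amplitude T-wave quantities
    win = max(5, int(round(0.06 * beat.fs)) | 1)
    rt = scipy.signal.savgol_filter(rms, min(win, n - 1 - (n % 2 == 0)), 3)
    rt = np.sqrt(np.clip(rt**2 - floor**2, 0.0, None))

    qpk = int(np.argmax(r))
    qlvl = isoline_fraction * r[qpk]
    qrs_beg = _cross_up_back(r, qpk, qlvl)
    t_end_qrs = _cross_down(r, qpk, qlvl)
    if t_end_qrs is None:
        raise SegmentationError("QRS lobe never returns to the isoline")
    qrs_end = t_end_qrs

    lo = qrs_end + int(round(refractory_s * beat.fs))
    hi = min(n, qrs_end + int(round(t_search_s * beat.fs)))
    if hi - lo < 5:
        raise SegmentationError("no room for a T-wave after the QRS complex")
    t_max = lo + int(np.argmax(rt[lo:hi]))
    if rt[t_max] <= qlvl:
        raise SegmentationError("no T-wave lobe above the isoline")

    # T onset: steepest upstroke of the lobe that rises into t_max.  The
    # search starts after the last local minimum of R before the T peak so
    # that an ST injury-current bump cannot masquerade as the T upstroke.
    dr = scipy.signal.savgol_filter(rms, min(win, n - 1 - (n % 2 == 0)), 3, deriv=1)
    minima = scipy.signal.argrelmin(rt[qrs_end + 1 : t_max + 1], order=3)[0]
    rise_start = qrs_end + 1 + (int(minima[-1]) if len(minima) else 0)
    t_beg = rise_start + int(np.argmax(dr[rise_start : t_max + 1]))
    t_beg = max(t_beg, qrs_end)

    tlvl = isoline_fraction * rt[t_max]
    t_end = _cross_down(rt, t_max, tlvl)
    if t_end is None:
        raise SegmentationError("T-wave never returns to the isoline")
    try:
        return Segmentation(qrs_beg, qrs_end, t_beg, t_max, t_end)
    except ValueError as exc:  # ordering violated -> morphology not beat-like
        raise SegmentationError(str(exc)) from exc


def heart_rate(onsets: np.ndarray, fs: float) -> float:
    """Heart rate in beats per minute from the median inter-beat interval."""
    onsets = np.asarray(onsets)
    if len(onsets) < 2:
        raise InsufficientBeatsError("need at least 2 beats for a heart rate")
    return 60.0 * fs / float(np.median(np.diff(onsets)))
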