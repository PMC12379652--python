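"""Conventional MCG parameters and the Total Score.

The Total Score combines four repolarization parameters — the ST-T analysis
(current moment dynamics, pole distance dynamics, current angle dynamics),
T-dispersion, vector-MCG trajectory closure (VMCG) and the monopolarity
trend (PLP) — into a 0-10 (rest) / 0-20 (rest+stress) score, pathologic at
two points or more.  ST-T analysis and T-dispersion are the main
parameters; VMCG and PLP are enhancers that only count once a main
parameter has scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import AveragedBeat, Segmentation

__all__ = [
    "ScoreBreakdown",
    "ScoreThresholds",
    "current_moment_dynamics",
    "current_moment_increase",
    "max_convex_slope",
    "t_dispersion",
    "average_rms_segment",
    "stt_score",
    "vmcg_score",
    "plp_score",
    "plp_trend",
    "total_score",
    "classify_pathologic",
    "MAXIMA",
]

# default per-phase point allocation: 3 + 3 + 2 + 2 = 10
MAXIMA = {"stt": 3, "tdisp": 3, "vmcg": 2, "plp": 2}


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-phase Total Score decomposition."""

    stt_score: int
    tdisp_score: int
    vmcg_score: int
    plp_score: int
    total: int
    phase: str = "rest"


@dataclass(frozen=True)
class ScoreThresholds:
    """Reference distribution (mean, sd) per raw parameter for z-scoring.

    A raw parameter is graded against these healthy-calibration constants:
    a value is abnormal when its absolute z-score strictly exceeds a grade
    cut-off (1.96 for the first point, 2.58 / 3.29 for further points on
    graded components).  Values exactly at a cut-off score nothing.
    """

    cmd: tuple[float, float]
    pdd: tuple[float, float]
    cad: tuple[float, float]
    tdisp: tuple[float, float]
    vmcg: tuple[float, float]
    plp_slope: tuple[float, float]

    def z(self, name: str, value: float) -> float:
        mean, sd = getattr(self, name)
        return (value - mean) / sd if sd > 0 else 0.0


GRADE_CUTS = (1.96, 2.58, 3.29)


def _grade(z: float, n_levels: int) -> int:
    """Points for |z| against the first ``n_levels`` grade cut-offs (strict >)."""
    return int(sum(abs(z) > c for c in GRADE_CUTS[:n_levels]))


def _slope_window(q: np.ndarray, a: int, b: int, fs: float):
    q = np.asarray(q, dtype=float)
    if b - a < 2:
        raise ValueError("window must span at least 3 samples")
    seg = q[a : b + 1]
    dq = np.gradient(seg) * fs          # central differences, units per second
    return seg, dq


def current_moment_dynamics(q: np.ndarray, seg: Segmentation, fs: float) -> float:
    """Maximum absolute slope of the dipole moment between T onset and T peak.

    ``q`` is indexed on the same sample axis as the segmentation; the window
    is [t_beg, t_max].  Units: moment units per second.
    """
    _, dq = _slope_window(q, seg.t_beg, seg.t_max, fs)
    return float(np.max(np.abs(dq)))


def max_convex_slope(y: np.ndarray, a: int, b: int, fs: float) -> float:
    """Maximum positive slope restricted to locally convex samples.

    A sample is locally convex when the second difference of ``y`` is >= 0;
    the result is the largest first derivative over convex samples with
    positive slope, or 0 when no sample qualifies.
    """
    seg, dq = _slope_window(y, a, b, fs)
    d2 = np.gradient(np.gradient(seg))
    ok = (d2 >= 0) & (dq > 0)
    return float(np.max(dq[ok])) if np.any(ok) else 0.0


def current_moment_increase(q: np.ndarray, seg: Segmentation, fs: float) -> float:
    """Maximum convex slope of the dipole moment on [t_beg, t_max]."""
    return max_convex_slope(q, seg.t_beg, seg.t_max, fs)


def t_dispersion(beat: AveragedBeat, seg: Segmentation,
                 amp_weight: float = 10.0, lat_weight: float = 0.1,
                 latency_amp_floor: float = 0.25) -> float:
    """Composite transmural repolarization dispersion measure.

    Two additive terms, both 0 for perfectly homogeneous channels:

    * amplitude heterogeneity at the T peak — robust coefficient of
      variation IQR/|median| of the per-channel absolute values at
      ``t_max``, clipped to [0, 3], times ``amp_weight``;
    * T-peak latency spread — standard deviation of the per-channel T-peak
      latencies in ms, times ``lat_weight`` (default ms/10).  Channels
      whose T-wave peak amplitude is below ``latency_amp_floor`` of the
      strongest channel sit near the dipolar field null, where a "latency"
      is dominated by sensor noise, so they are excluded from this term.
    """
    data = beat.beat[:, beat.channel_mask]
    if data.shape[1] < 2:
        raise ValueError("need at least 2 active channels")
    amp = np.abs(data[seg.t_max])
    med = np.median(amp)
    if np.ptp(amp) == 0 and np.ptp(data[seg.t_beg : seg.t_end + 1], axis=1).max() == 0:
        return 0.0
    q75, q25 = np.percentile(amp, [75, 25])
    cv = np.clip((q75 - q25) / med, 0.0, 3.0) if med > 0 else 3.0
    window = np.abs(data[seg.t_beg : seg.t_end + 1])
    peaks = window.max(axis=0)
    strong = peaks >= latency_amp_floor * peaks.max() if peaks.max() > 0 else peaks >= 0
    lat = np.argmax(window[:, strong], axis=0) / beat.fs * 1000.0  # ms
    return float(amp_weight * cv + lat_weight * np.std(lat))


def average_rms_segment(rms: np.ndarray, a: int, b: int) -> float:
    """Arithmetic mean of the RMS reference on the closed interval [a, b]."""
    if a > b:
        raise ValueError("empty segment: a > b")
    rms = np.asarray(rms, dtype=float)
    if b >= len(rms):
        raise ValueError("segment exceeds trace length")
    return float(np.mean(rms[a : b + 1]))


def stt_score(cmd: float, pdd: float, cad: float, thresholds: ScoreThresholds) -> int:
    """ST-T analysis score: one point per abnormal component (0-3).

    Components: current moment dynamics, pole distance dynamics, current
    angle dynamics, each z-scored against the healthy reference and counted
    abnormal at |z| > 1.96.
    """
    for v, name in ((cmd, "cmd"), (pdd, "pdd"), (cad, "cad")):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing ST-T component {name}")
    return sum(
        _grade(thresholds.z(name, v), 1)
        for v, name in ((cmd, "cmd"), (pdd, "pdd"), (cad, "cad"))
    )


def tdisp_score(tdisp: float, thresholds: ScoreThresholds) -> int:
    """T-dispersion score, graded 0-3 against the healthy reference."""
    return _grade(thresholds.z("tdisp", tdisp), MAXIMA["tdisp"])


def vmcg_closure_distance(trajectory: np.ndarray) -> float:
    """Distance between start and end of the dipole trajectory (closure).

    In a continuous, healthy repolarization loop the trajectory should
    return to its origin, so the closure distance should be near 0.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or len(trajectory) < 2:
        raise ValueError("trajectory needs at least 2 points")
    return float(np.linalg.norm(trajectory[0] - trajectory[-1]))


def vmcg_score(trajectory: np.ndarray, thresholds: ScoreThresholds) -> int:
    """VMCG score, graded 0-2 on the z-scored trajectory closure distance."""
    return _grade(thresholds.z("vmcg", vmcg_closure_distance(trajectory)),
                  MAXIMA["vmcg"])


def plp_trend(m_t: np.ndarray, fs: float) -> float:
    """Least-squares slope of M(t) over the ST-T segment, per second."""
    m_t = np.asarray(m_t, dtype=float)
    if len(m_t) < 3:
        raise ValueError("need at least 3 samples for a trend")
    t = np.arange(len(m_t)) / fs
    return float(np.polyfit(t, m_t, 1)[0])


def plp_score(m_t: np.ndarray, fs: float, thresholds: ScoreThresholds) -> int:
    """PLP score, graded 0-2 on the monopolarity trend over ST-T.

    An upward or downward trend of M(t) reflects a growing or shrinking
    proportion of injury current during repolarization.
    """
    return _grade(thresholds.z("plp_slope", plp_trend(m_t, fs)), MAXIMA["plp"])


def total_score(stt: int, tdisp: int, vmcg: int, plp: int,
                phase: str = "rest") -> ScoreBreakdown:
    """Combine component points into the per-phase Total Score.

    The enhancer rule: VMCG and PLP enter the sum only if at least one main
    parameter (ST-T analysis or T-dispersion) has at least one point.
    """
    for v, name in ((stt, "stt"), (tdisp, "tdisp"), (vmcg, "vmcg"), (plp, "plp")):
        if not (0 <= v <= MAXIMA[name]):
            raise ValueError(f"{name} score {v} outside [0, {MAXIMA[name]}]")
    enhancers = vmcg + plp if (stt >= 1 or tdisp >= 1) else 0
    return ScoreBreakdown(stt, tdisp, vmcg, plp, stt + tdisp + enhancers, phase)


def classify_pathologic(total: float) -> bool:
    """Pathologic finding: Total Score of at least two points."""
    if total < 0:
        raise ValueError("total score cannot be negative")
    return total >= 2
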