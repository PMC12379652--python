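"""Magnetoionography (MIG) parameters.

MIG splits the RMS reference signal R(t) into a dipolar ionic-flux function
I(t) = R(t)*D(t) and a monopolar ionic-flux function J(t) = R(t)*M(t),
using the field-map dipolarity D(t) = 1 - M(t) as a per-sample weight.
Segment averages of I and J quantify the dipolar (axial, rectified) versus
diffuse portion of the repolarization current; the maximum convex slope of
I(t) between QRS end and T peak is reported as the Calcium Release
Velocity (a label for the putative intracellular Ca2+ flux component — no
literal ionic current is measured).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcg_params import max_convex_slope
from .signal_core import Segmentation

__all__ = [
    "IonicFluxTrace",
    "ionic_flux",
    "flux_segment_average",
    "calcium_release_velocity",
]


@dataclass
class IonicFluxTrace:
    """Dipolar I(t) and monopolar J(t) ionic-flux functions."""

    i_t: np.ndarray
    j_t: np.ndarray
    fs: float

    def __post_init__(self):
        self.i_t = np.asarray(self.i_t, dtype=float)
        self.j_t = np.asarray(self.j_t, dtype=float)


def ionic_flux(rms: np.ndarray, m_t: np.ndarray, fs: float,
               operator: str = "product") -> IonicFluxTrace:
    """Combine R(t) with the monopolarity index M(t) into I(t) and J(t).

    The default ``product`` operator is the pointwise weighting
    ``i_t = R*(1-M)``, ``j_t = R*M``, which conserves ``i_t + j_t = R``
    exactly and matches the "index x RMS" naming of the exported segment
    averages.  A ``convolution`` variant (full discrete convolution cropped
    to the input length) is provided as an alternative reading.
    """
    rms = np.asarray(rms, dtype=float)
    m_t = np.asarray(m_t, dtype=float)
    if rms.shape != m_t.shape:
        raise ValueError("R(t) and M(t) must have equal length")
    if np.any((m_t < 0) | (m_t > 1)):
        raise ValueError("M(t) must lie in [0, 1]")
    d_t = 1.0 - m_t
    if operator == "product":
        return IonicFluxTrace(i_t=rms * d_t, j_t=rms * m_t, fs=fs)
    if operator == "convolution":
        n = len(rms)
        return IonicFluxTrace(
            i_t=np.convolve(rms, d_t, mode="full")[:n],
            j_t=np.convolve(rms, m_t, mode="full")[:n],
            fs=fs,
        )
    raise ValueError(f"unknown flux operator {operator!r}")


def flux_segment_average(trace: IonicFluxTrace, which: str, a: int, b: int) -> float:
    """Arithmetic mean of the selected flux on the closed interval [a, b].

    ``which`` selects ``"dipolar"`` (I) or ``"monopolar"`` (J).  Named
    exports built on this: dipolar mean on [qrs_end, t_beg] is the
    Dipolarity Index for the ST segment; monopolar means on the QRS complex
    and on [t_beg, t_end] are the QRS-interval and T-wave indices.
    """
    if which == "dipolar":
        y = trace.i_t
    elif which == "monopolar":
        y = trace.j_t
    else:
        raise ValueError(f"which must be 'dipolar' or 'monopolar', got {which!r}")
    if a > b:
        raise ValueError("empty segment: a > b")
    if b >= len(y):
        raise ValueError("segment exceeds trace length")
    return float(np.mean(y[a : b + 1]))


def calcium_release_velocity(trace: IonicFluxTrace, seg: Segmentation) -> float:
    """Maximum convex slope of I(t) between QRS end and T peak.

    Same convex-slope operator as the Current Moment Increase, applied to
    the dipolar ionic flux; units are signal units per second.
    """
    if seg.qrs_end >= seg.t_max:
        raise ValueError("QRS end must precede the T peak")
    return max_convex_slope(trace.i_t, seg.qrs_end, seg.t_max, trace.fs)
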