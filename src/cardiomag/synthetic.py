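"""Physics-based synthetic MCG generator.

Beats are synthesised in field space from equivalent current dipoles under
the sensor array (Biot-Savart forward model): the QRS complex is a strong,
fast-rotating dipole; the T wave a slower dipole whose amplitude, latency
homogeneity and dipolarity are the phenotype dials.  A CAD-like phenotype
adds a spatially diffuse single-sign "injury current" patch during the ST-T
segment (raising the monopolarity index), lowers the T amplitude, spreads
per-channel T-peak latencies and blunts the stress heart-rate response.
Every beat comes with ground-truth fiducials so each downstream operation
can be validated against a known answer.

Default phenotype constants live in ``data/phenotypes.yaml`` (data, not
code) and emulate the healthy-vs-CAD contrasts of the reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .fieldmap import _dipole_kernel
from .signal_core import MultiChannelRecording, Segmentation, SensorGrid

__all__ = [
    "PhenotypeParams",
    "CohortSpec",
    "forward_biot_savart",
    "simulate_beat",
    "simulate_recording",
    "simulate_cohort",
    "default_phenotypes",
]


def forward_biot_savart(position, moment, depth: float, grid: SensorGrid,
                        component: str = "z") -> np.ndarray:
    """Field of a tangential current dipole at every sensor.

    ``position`` is the (x, y) of the dipole in the sensor plane's
    coordinates, ``depth`` its distance below the plane (m), ``moment`` the
    tangential moment vector (qx, qy) in A*m.  Returns the chosen Cartesian
    field component per channel, in tesla; linear in the moment.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    K = _dipole_kernel(grid, np.asarray(position, dtype=float), depth, component)
    return K @ np.asarray(moment, dtype=float)


@dataclass(frozen=True)
class PhenotypeParams:
    """Generator dials for one subject class."""

    t_amplitude_scale: float = 1.0
    injury_current_fraction: float = 0.0
    t_peak_jitter_ms: float = 0.0
    hr_rest_bpm: float = 70.0
    hr_stress_bpm: float = 103.0
    hr_sd_bpm: float = 10.0         # inter-subject heart-rate spread
    noise_sd: float = 0.15          # pT
    dipole_depth_m: float = 0.06
    stress_t_gain: float = 1.10     # T-amplitude amplification under stress
    qrs_moment: float = 3.0e-6      # A*m, ~27 pT peak channel at 60 mm depth
    t_moment: float = 0.54e-6       # A*m before t_amplitude_scale
    # repolarization source sits off the array centre, as over a real chest:
    # the truncated field map then has the moderate monopolarity (~0.2) seen
    # in healthy T-waves instead of a perfectly balanced +/- pattern
    t_dipole_offset: tuple = (0.035, -0.025)

    def __post_init__(self):
        if not 0.0 <= self.injury_current_fraction <= 1.0:
            raise ValueError("injury_current_fraction must lie in [0, 1]")
        for name in ("t_amplitude_scale", "t_peak_jitter_ms", "hr_rest_bpm",
                     "hr_stress_bpm", "noise_sd", "dipole_depth_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortSpec:
    """Cohort layout: class sizes, phenotypes, geometry and master seed."""

    n_healthy: int = 36
    n_cad: int = 93
    phenotypes: dict = field(default_factory=lambda: default_phenotypes())
    fs: float = 500.0
    grid: SensorGrid = field(default_factory=SensorGrid.regular)
    master_seed: int = 0
    duration_s: float = 30.0

    def __post_init__(self):
        if self.n_healthy < 1 or self.n_cad < 1:
            raise ValueError("both class counts must be >= 1")


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """Healthy / CAD phenotype defaults shipped as package data."""
    text = resources.files("cardiomag.data").joinpath("phenotypes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {k: PhenotypeParams(**v) for k, v in raw.items()}


_GAUSS_CUT = np.sqrt(2.0 * np.log(20.0))  # 5%-of-peak half-width in sigmas


def _injury_pattern(grid: SensorGrid, center=(0.0, 0.0)) -> np.ndarray:
    """Broad single-sign Gaussian patch (sigma = 3 sensor spacings)."""
    sigma = 3.0 * grid.spacing
    r2 = np.sum((grid.positions - np.asarray(center)) ** 2, axis=1)
    return np.exp(-r2 / (2.0 * sigma**2))


def _beat_template(phenotype: PhenotypeParams, grid: SensorGrid, fs: float,
                   rr_s: float, phase: str, rng: np.random.Generator):
    """Noise-free one-beat field matrix plus ground-truth fiducials.

    The beat axis starts 300 ms before the R peak.  Returns
    ``(beat, truth, r_peak_index)``.
    """
    qrs_c = int(round(0.30 * fs))
    t_offset = min(0.30, 0.45 * rr_s)                      # QT shortens with RR
    t_c = qrs_c + int(round(t_offset * fs))
    sigma_q = 0.015 * fs                                   # samples
    sigma_t = 0.042 * np.sqrt(rr_s / 0.857) * fs
    n = t_c + int(round(2.448 * sigma_t)) + int(round(0.12 * fs))
    t = np.arange(n)

    # QRS: rotating tangential dipole, Gaussian amplitude envelope
    env_q = np.exp(-((t - qrs_c) ** 2) / (2 * sigma_q**2))
    theta = np.deg2rad(-60.0 + 180.0 * (t - qrs_c) / (6 * sigma_q))
    mom_q = phenotype.qrs_moment * env_q[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    K = _dipole_kernel(grid, np.zeros(2), phenotype.dipole_depth_m, "z")
    beat = (mom_q @ K.T) * 1e12                            # tesla -> pT

    # T wave: slower dipole with a fixed axis and per-channel latency jitter
    t_amp = phenotype.t_amplitude_scale * phenotype.t_moment
    if phase == "stress":
        t_amp *= phenotype.stress_t_gain
    axis = np.array([np.cos(np.deg2rad(40.0)), np.sin(np.deg2rad(40.0))])
    K_t = _dipole_kernel(grid, np.asarray(phenotype.t_dipole_offset, dtype=float),
                         phenotype.dipole_depth_m, "z")
    p_dip = (K_t @ (t_amp * axis)) * 1e12                  # pT per unit envelope
    jitter = rng.normal(0.0, phenotype.t_peak_jitter_ms / 1000.0 * fs,
                        size=grid.n_channels)
    env_t = np.exp(-((t[:, None] - t_c - jitter[None, :]) ** 2) / (2 * sigma_t**2))
    dip_field = p_dip[None, :] * env_t

    # injury current: spatially diffuse single-sign patch active over the ST
    # segment (plateau phase), energy-matched to the dipolar T over ST-T so
    # that injury_current_fraction is the injury's share of ST-T energy
    f = phenotype.injury_current_fraction
    patch = _injury_pattern(grid, phenotype.t_dipole_offset)
    qrs_end_nom = qrs_c + _GAUSS_CUT * sigma_q
    t_beg_nom = t_c - sigma_t
    inj_c = 0.5 * (qrs_end_nom + t_beg_nom)
    sigma_i = 0.035 * fs
    env_i = np.exp(-((t - inj_c) ** 2) / (2 * sigma_i**2))
    inj_field = patch[None, :] * env_i[:, None]
    stt = slice(int(round(qrs_end_nom)),
                int(round(t_c + _GAUSS_CUT * sigma_t)) + 1)
    env_t0 = np.exp(-((t - t_c) ** 2) / (2 * sigma_t**2))  # jitterless reference
    e_dip = np.sum((p_dip[None, :] * env_t0[:, None])[stt] ** 2)
    e_inj = np.sum(inj_field[stt] ** 2)
    inj_field *= np.sqrt(e_dip / e_inj)
    beat += np.sqrt(1.0 - f) * dip_field + np.sqrt(f) * inj_field
    truth = _operational_fiducials(beat, fs)
    return beat, truth, qrs_c


def _operational_fiducials(clean_beat: np.ndarray, fs: float) -> Segmentation:
    """Ground-truth fiducials: the operational definitions on noiseless R(t).

    5%-of-peak interpolated crossings bracket the QRS lobe and terminate the
    T wave; the T peak is the R(t) argmax in the physiologic search window;
    T onset is the steepest upstroke of the lobe rising into the T peak.
    Because the beat is noise-free, no smoothing or noise-floor handling is
    involved — this is the exact answer the segmenter tries to recover from
    noisy data.
    """
    from .signal_core import _cross_down, _cross_up_back

    r = np.sqrt(np.mean(clean_beat**2, axis=1))
    qpk = int(np.argmax(r))
    qlvl = 0.05 * r[qpk]
    qrs_beg = _cross_up_back(r, qpk, qlvl)
    qrs_end = _cross_down(r, qpk, qlvl)
    lo = qrs_end + int(round(0.08 * fs))
    hi = min(len(r), qrs_end + int(round(0.40 * fs)))
    t_max = lo + int(np.argmax(r[lo:hi]))
    import scipy.signal as _sig

    minima = _sig.argrelmin(r[qrs_end + 1 : t_max + 1], order=3)[0]
    rise = qrs_end + 1 + (int(minima[-1]) if len(minima) else 0)
    dr = np.gradient(r)
    t_beg = rise + int(np.argmax(dr[rise : t_max + 1]))
    t_end = _cross_down(r, t_max, 0.05 * r[t_max])
    return Segmentation(qrs_beg, qrs_end, max(t_beg, qrs_end), t_max, t_end)


def simulate_beat(phenotype: PhenotypeParams, grid: SensorGrid | None = None,
                  fs: float = 500.0, phase: str = "rest",
                  seed: int | np.random.SeedSequence = 0):
    """One synthetic beat as a recording, with ground-truth fiducials.

    The same seed always yields a bit-identical beat.
    """
    grid = grid or SensorGrid.regular()
    rng = np.random.default_rng(seed)
    hr = phenotype.hr_rest_bpm if phase == "rest" else phenotype.hr_stress_bpm
    hr = max(40.0, rng.normal(hr, phenotype.hr_sd_bpm))
    beat, truth, _ = _beat_template(phenotype, grid, fs, 60.0 / hr, phase, rng)
    if phenotype.noise_sd > 0:
        beat = beat + rng.normal(0.0, phenotype.noise_sd, size=beat.shape)
    rec = MultiChannelRecording(data=beat, fs=fs, grid=grid, phase=phase)
    return rec, truth


def simulate_recording(phenotype: PhenotypeParams, grid: SensorGrid | None = None,
                       fs: float = 500.0, phase: str = "rest",
                       duration_s: float = 30.0,
                       seed: int | np.random.SeedSequence = 0):
    """Multi-beat recording: the subject's beat tiled at the phase's RR.

    The per-channel T-latency jitter is drawn once per recording (a subject
    property, identical across beats); white sensor noise is drawn per
    sample.  Returns ``(recording, truth, r_peak_indices)`` where ``truth``
    holds the fiducials relative to each beat's R peak minus 300 ms.
    """
    grid = grid or SensorGrid.regular()
    rng = np.random.default_rng(seed)
    hr = phenotype.hr_rest_bpm if phase == "rest" else phenotype.hr_stress_bpm
    hr = max(40.0, rng.normal(hr, phenotype.hr_sd_bpm))
    rr = int(round(60.0 / hr * fs))
    beat, truth, qrs_c = _beat_template(phenotype, grid, fs, 60.0 / hr, phase, rng)
    n = int(round(duration_s * fs))
    if n < rr * 3:
        raise ValueError("duration too short for at least 2 full beats")
    data = np.zeros((n, grid.n_channels))
    peaks = []
    start = int(round(0.4 * fs)) - qrs_c
    while start + len(beat) <= n:
        data[start : start + len(beat)] += beat
        peaks.append(start + qrs_c)
        start += rr
    if phenotype.noise_sd > 0:
        data += rng.normal(0.0, phenotype.noise_sd, size=data.shape)
    rec = MultiChannelRecording(data=data, fs=fs, grid=grid, phase=phase)
    return rec, truth, np.asarray(peaks)


def _subject_seed(master_seed: int, index: int, phase: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, index, 0 if phase == "rest" else 1])


def simulate_cohort(spec: CohortSpec):
    """Paired rest/stress recordings for every subject in the cohort.

    Yields dicts ``{subject, label, phase, recording, truth, r_peaks}`` in a
    deterministic order; per-subject seeds are derived from
    ``(master_seed, subject index, phase)`` so any subject can be
    regenerated in isolation.
    """
    labels = ["healthy"] * spec.n_healthy + ["CAD"] * spec.n_cad
    for idx, label in enumerate(labels):
        phenotype = spec.phenotypes[label]
        subject = f"{'H' if label == 'healthy' else 'P'}{idx:03d}"
        for phase in ("rest", "stress"):
            rec, truth, peaks = simulate_recording(
                phenotype, spec.grid, spec.fs, phase, spec.duration_s,
                seed=_subject_seed(spec.master_seed, idx, phase),
            )
            yield {
                "subject": subject,
                "label": label,
                "phase": phase,
                "recording": rec,
                "truth": truth,
                "r_peaks": peaks,
            }
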