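"""End-to-end parameter extraction: recording -> per-subject feature row.

Realises the full analysis chain: band-pass filtering, beat detection and
averaging, segmentation, field-map / dipole-inversion parameters over the
ST-T segment, MIG ionic-flux parameters, and the Total Score, exported
with cohort-table column names (``<Parameter>_<phase>``).
"""

from __future__ import annotations

import logging


import numpy as np
import pandas as pd

from . import fieldmap, mcg_params, mig_params, signal_core
from .config import PipelineConfig, default_score_thresholds
from .mcg_params import ScoreThresholds
from .signal_core import MultiChannelRecording

log = logging.getLogger(__name__)

__all__ = ["extract_phase_parameters", "extract_subject", "extract_cohort",
           "PARAMETER_COLUMNS"]

# moment slopes are exported in units of 1/3 uA*m/s so cohort tables sit at
# a readable O(10) magnitude
MOMENT_SLOPE_SCALE = 3e6

PARAMETER_COLUMNS = [
    "HeartRate",
    "PoleDistanceDynamics",
    "CurrentAngleDynamics",
    "CurrentMomentDynamics",
    "CurrentMomentIncrease",
    "Tdispersion",
    "AverageRmsTbegtoTend",
    "AverageRmsSt",
    "VmcgTDistance",
    "PlpTrend",
    "CalciumReleaseVelocity",
    "AverageMIxRmsQrsInterval",
    "AverageMIxRmsTbegtoTend",
    "DipolarityIndexForST",
    "SttScore",
    "TdispScore",
    "VmcgScore",
    "PlpScore",
    "TotalScore",
]


def extract_phase_parameters(rec: MultiChannelRecording,
                             config: PipelineConfig | None = None,
                             thresholds: ScoreThresholds | None = None) -> dict:
    """All MCG + MIG parameters and score components for one recording."""
    cfg = config or PipelineConfig()
    thr = thresholds or default_score_thresholds()

    filtered = signal_core.filter_recording(
        rec, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order
    )
    onsets = signal_core.detect_beats(filtered)
    hr = signal_core.heart_rate(onsets, rec.fs)
    beat = signal_core.isoline_correct(signal_core.average_beats(filtered, onsets))
    seg = signal_core.segment_beat(beat, isoline_fraction=cfg.isoline_fraction)

    stt_idx = np.arange(seg.qrs_end, seg.t_end + 1)
    # recordings are in pT; the dipole kernel works in SI units
    trace, snaps = fieldmap.fit_moment_trace(
        beat.beat[:, beat.channel_mask] * 1e-12, _masked_grid(beat), stt_idx, beat.fs,
        depth=cfg.dipole_depth_m, n_pos=cfg.dipole_positions,
        upsample=cfg.map_upsample, snapshots=True,
    )
    # q(t) indexed on the full beat axis for the slope operators
    q_full = np.zeros(beat.n_samples)
    q_full[stt_idx] = trace.q

    m_t = fieldmap.monopolarity_trace(beat.beat, beat.channel_mask,
                                      cfg.monopolarity_variant)
    m_stt = m_t[stt_idx]
    flux = mig_params.ionic_flux(beat.rms, np.clip(m_t, 0.0, 1.0), beat.fs,
                                 operator=cfg.flux_operator)

    cmd = mcg_params.current_moment_dynamics(q_full, seg, beat.fs)
    cmi = mcg_params.current_moment_increase(q_full, seg, beat.fs)
    pdd = fieldmap.pole_distance_dynamics(snaps)
    cad = fieldmap.current_angle_dynamics(snaps)
    tdisp = mcg_params.t_dispersion(beat, seg)
    plp_slope = mcg_params.plp_trend(m_stt, beat.fs)
    vmcg_closure = mcg_params.vmcg_closure_distance(trace.position)

    stt_pts = mcg_params.stt_score(cmd * MOMENT_SLOPE_SCALE, pdd, cad, thr)
    tdisp_pts = mcg_params.tdisp_score(tdisp, thr)
    vmcg_pts = mcg_params.vmcg_score(trace.position, thr)
    plp_pts = mcg_params.plp_score(m_stt, beat.fs, thr)
    score = mcg_params.total_score(stt_pts, tdisp_pts, vmcg_pts, plp_pts,
                                   phase=rec.phase)

    return {
        "HeartRate": hr,
        "PoleDistanceDynamics": pdd,
        "CurrentAngleDynamics": cad,
        "CurrentMomentDynamics": cmd * MOMENT_SLOPE_SCALE,
        "CurrentMomentIncrease": cmi * MOMENT_SLOPE_SCALE,
        "Tdispersion": tdisp,
        "AverageRmsTbegtoTend": mcg_params.average_rms_segment(
            beat.rms, seg.t_beg, seg.t_end),
        "AverageRmsSt": mcg_params.average_rms_segment(
            beat.rms, seg.qrs_end, seg.t_beg),
        "VmcgTDistance": vmcg_closure,
        "PlpTrend": plp_slope,
        "CalciumReleaseVelocity": mig_params.calcium_release_velocity(flux, seg),
        "AverageMIxRmsQrsInterval": mig_params.flux_segment_average(
            flux, "monopolar", seg.qrs_beg, seg.qrs_end),
        "AverageMIxRmsTbegtoTend": mig_params.flux_segment_average(
            flux, "monopolar", seg.t_beg, seg.t_end),
        "DipolarityIndexForST": mig_params.flux_segment_average(
            flux, "dipolar", seg.qrs_end, seg.t_beg),
        "SttScore": stt_pts,
        "TdispScore": tdisp_pts,
        "VmcgScore": vmcg_pts,
        "PlpScore": plp_pts,
        "TotalScore": score.total,
    }


def _masked_grid(beat) -> "signal_core.SensorGrid":
    if beat.channel_mask.all():
        return beat.grid
    # dipole fitting tolerates missing channels; map interpolation does not,
    # so a masked grid is only valid when it stays rectangular
    raise NotImplementedError(
        "field-map parameters require the full rectangular grid; "
        "interpolate or drop masked subjects upstream"
    )


def extract_subject(recordings: dict[str, MultiChannelRecording],
                    config: PipelineConfig | None = None,
                    thresholds: ScoreThresholds | None = None) -> dict:
    """Feature row for one subject from its rest/stress recording pair.

    Missing phases are allowed; their columns are absent.  The combined
    TotalScore column sums the per-phase totals (0-20 when both phases are
    present).
    """
    row: dict = {}
    total = 0
    for phase, rec in recordings.items():
        params = extract_phase_parameters(rec, config, thresholds)
        total += params["TotalScore"]
        row.update({f"{k}_{phase}": v for k, v in params.items()})
    row["TotalScoreCombined"] = total
    row["Pathologic"] = mcg_params.classify_pathologic(total)
    return row


def extract_cohort(subjects, config: PipelineConfig | None = None,
                   thresholds: ScoreThresholds | None = None):
    """Feature table for an iterable of simulated/loaded cohort entries.

    ``subjects`` yields dicts with keys ``subject``, ``label``, ``phase``,
    ``recording`` (as produced by :func:`cardiomag.synthetic.simulate_cohort`).
    Subjects whose extraction fails land in the returned failures frame and
    the run continues.
    """
    per_subject: dict[str, dict] = {}
    for entry in subjects:
        per_subject.setdefault(entry["subject"], {"label": entry["label"],
                                                  "recordings": {}})
        per_subject[entry["subject"]]["recordings"][entry["phase"]] = entry["recording"]

    rows, failures = [], []
    for subject, info in per_subject.items():
        try:
            row = extract_subject(info["recordings"], config, thresholds)
        except Exception as exc:  # noqa: BLE001 - pipeline must survive bad subjects
            log.warning("extraction failed for %s: %s", subject, exc)
            failures.append({"subject": subject, "error": str(exc)})
            continue
        row["subject"] = subject
        row["label"] = info["label"]
        rows.append(row)
    features = pd.DataFrame(rows)
    if not features.empty:
        lead = ["subject", "label"]
        features = features[lead + [c for c in features.columns if c not in lead]]
    return features, pd.DataFrame(failures, columns=["subject", "error"])
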