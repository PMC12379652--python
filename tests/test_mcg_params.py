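"""MCG parameters, score components and Total Score arithmetic."""

import itertools

import numpy as np
import pytest

import cardiomag as cm
from cardiomag.mcg_params import (
    MAXIMA,
    ScoreThresholds,
    max_convex_slope,
    plp_trend,
    tdisp_score,
    vmcg_closure_distance,
)
from cardiomag.signal_core import Segmentation
from conftest import make_beat

FS = 500.0

# unit-variance reference centred at 0: z equals the raw value
UNIT_THRESHOLDS = ScoreThresholds(
    cmd=(0.0, 1.0), pdd=(0.0, 1.0), cad=(0.0, 1.0),
    tdisp=(0.0, 1.0), vmcg=(0.0, 1.0), plp_slope=(0.0, 1.0),
)


# ------------------------------------------------------- moment slope operators

def test_moment_dynamics_linear_trace_gives_slope():
    k = np.arange(300)
    q = 4.0 * k / FS  # slope 4 per second
    seg = Segmentation(0, 1, 10, 200, 250)
    assert cm.current_moment_dynamics(q, seg, FS) == pytest.approx(4.0)


def test_moment_dynamics_constant_trace_is_zero():
    seg = Segmentation(0, 1, 10, 200, 250)
    assert cm.current_moment_dynamics(np.full(300, 2.5), seg, FS) == 0.0


def test_moment_dynamics_sine_quarter_period():
    k = np.arange(300)
    q = np.sin(2 * np.pi * k / FS)  # 1 Hz, max derivative 2*pi at k=0
    seg = Segmentation(0, 1, 1, 126, 127)
    assert cm.current_moment_dynamics(q, seg, FS) == pytest.approx(2 * np.pi, rel=0.01)


def test_moment_dynamics_window_too_short():
    with pytest.raises(ValueError):
        cm.current_moment_dynamics(np.arange(10.0), Segmentation(0, 1, 5, 6, 7), FS)


def test_moment_increase_concave_trace_is_zero():
    k = np.arange(300)
    q = np.sqrt(k + 1.0)  # strictly concave increasing
    seg = Segmentation(0, 1, 10, 200, 250)
    assert cm.current_moment_increase(q, seg, FS) == 0.0


def test_moment_increase_quadratic_trace():
    k = np.arange(300)
    q = (k / FS) ** 2  # slope 2t, convex everywhere
    seg = Segmentation(0, 1, 1, 250, 251)
    expected = 2.0 * 250 / FS
    assert cm.current_moment_increase(q, seg, FS) == pytest.approx(expected, rel=0.02)


def test_moment_increase_constant_is_zero():
    seg = Segmentation(0, 1, 10, 200, 250)
    assert cm.current_moment_increase(np.full(300, 1.0), seg, FS) == 0.0


def test_dynamics_bounds_increase_on_random_traces():
    """max |slope| >= max convex positive slope >= 0 on arbitrary traces."""
    rng = np.random.default_rng(3)
    seg = Segmentation(0, 1, 5, 150, 160)
    for _ in range(50):
        q = np.cumsum(rng.normal(size=200))
        cmd = cm.current_moment_dynamics(q, seg, FS)
        cmi = cm.current_moment_increase(q, seg, FS)
        assert cmd >= cmi >= 0.0


# ------------------------------------------------------- T dispersion

def _beat_with_peaks(latencies_ms, amps, n=400, sigma=10.0):
    t = np.arange(n)[:, None]
    centers = 200 + np.asarray(latencies_ms) / 1000.0 * FS
    data = np.asarray(amps) * np.exp(-((t - centers) ** 2) / (2 * sigma**2))
    return make_beat(data)


def test_t_dispersion_identical_channels_is_zero():
    beat = _beat_with_peaks([0, 0, 0, 0], [1, 1, 1, 1])
    seg = Segmentation(0, 1, 150, 200, 260)
    assert cm.t_dispersion(beat, seg) == 0.0


def test_t_dispersion_latency_term():
    """Two equal-amplitude groups 40 ms apart: std 20 ms -> latency term 2."""
    beat = _beat_with_peaks([-20, -20, 20, 20], [1, 1, 1, 1])
    seg = Segmentation(0, 1, 150, 200, 270)
    lat_only = cm.t_dispersion(beat, seg, amp_weight=0.0)
    assert lat_only == pytest.approx(2.0, abs=0.05)


def test_t_dispersion_amplitude_term_direct_formula():
    """Synchronous peaks {1,1,1,4}: term is 10 * IQR/median = 7.5."""
    beat = _beat_with_peaks([0, 0, 0, 0], [1.0, 1.0, 1.0, 4.0])
    seg = Segmentation(0, 1, 150, 200, 260)
    amp_only = cm.t_dispersion(beat, seg, lat_weight=0.0)
    amps = np.array([1.0, 1.0, 1.0, 4.0])
    q75, q25 = np.percentile(amps, [75, 25])
    expected = 10.0 * np.clip((q75 - q25) / np.median(amps), 0, 3)
    assert amp_only == pytest.approx(expected)
    assert expected == pytest.approx(7.5)


def test_t_dispersion_needs_two_channels():
    beat = _beat_with_peaks([0], [1])
    with pytest.raises(ValueError):
        cm.t_dispersion(beat, Segmentation(0, 1, 150, 200, 260))


# ------------------------------------------------------- segment averages

@pytest.mark.parametrize(
    "rms, a, b, expected",
    [([1.0, 2.0, 3.0], 0, 2, 2.0), ([5.0] * 10, 2, 7, 5.0)],
)
def test_average_rms_segment(rms, a, b, expected):
    assert cm.average_rms_segment(np.array(rms), a, b) == pytest.approx(expected)


def test_average_rms_segment_empty_raises():
    with pytest.raises(ValueError):
        cm.average_rms_segment(np.arange(10.0), 5, 3)


# ------------------------------------------------------- score components

def test_stt_score_counts_abnormal_components():
    assert cm.stt_score(0.0, 0.0, 0.0, UNIT_THRESHOLDS) == 0
    assert cm.stt_score(3.0, 0.0, 0.0, UNIT_THRESHOLDS) == 1
    assert cm.stt_score(3.0, -3.0, 5.0, UNIT_THRESHOLDS) == 3
    with pytest.raises(ValueError):
        cm.stt_score(np.nan, 0.0, 0.0, UNIT_THRESHOLDS)


def test_vmcg_closed_loop_scores_zero():
    loop = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
    assert vmcg_closure_distance(loop) == 0.0
    assert cm.vmcg_score(loop, UNIT_THRESHOLDS) == 0


def test_vmcg_open_trajectory_scores():
    open_traj = np.array([[0.0, 0.0], [5.0, 0.0]])
    assert cm.vmcg_score(open_traj, UNIT_THRESHOLDS) >= 1


def test_vmcg_exactly_at_threshold_scores_zero():
    traj = np.array([[0.0, 0.0], [1.96, 0.0]])  # |z| == 1.96, strict >
    assert cm.vmcg_score(traj, UNIT_THRESHOLDS) == 0


def test_plp_constant_monopolarity_scores_zero():
    assert cm.plp_score(np.full(100, 0.4), FS, UNIT_THRESHOLDS) == 0


def test_plp_strong_trend_scores():
    m = np.linspace(0.1, 0.9, 150)
    assert plp_trend(m, FS) == pytest.approx(0.8 / (149 / FS), rel=1e-6)
    assert cm.plp_score(m, FS, cm.default_score_thresholds()) >= 1


def test_plp_pure_noise_rarely_scores():
    """Trend-free monopolarity noise scores 0 in >= 95% of seeded draws."""
    thr = cm.default_score_thresholds()
    rng = np.random.default_rng(12345)
    zero = sum(
        cm.plp_score(np.clip(rng.normal(0.2, 0.05, 150), 0, 1), FS, thr) == 0
        for _ in range(200)
    )
    assert zero / 200 >= 0.95


def test_plp_too_few_samples():
    with pytest.raises(ValueError):
        cm.plp_score(np.array([0.1, 0.2]), FS, UNIT_THRESHOLDS)


# ------------------------------------------------------- total score

def test_total_score_examples():
    assert cm.total_score(0, 0, 0, 0).total == 0
    # enhancer rule: VMCG/PLP suppressed when both main parameters are 0
    assert cm.total_score(0, 0, 1, 1).total == 0
    assert cm.total_score(3, 3, 2, 2).total == 10


def test_total_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        cm.total_score(4, 0, 0, 0)


def test_total_score_enumeration_and_monotonicity():
    """Brute force over all component combinations: range, rule, monotone."""
    totals = set()
    combos = list(itertools.product(
        range(MAXIMA["stt"] + 1), range(MAXIMA["tdisp"] + 1),
        range(MAXIMA["vmcg"] + 1), range(MAXIMA["plp"] + 1),
    ))
    for stt, td, vm, pl in combos:
        total = cm.total_score(stt, td, vm, pl).total
        expected = stt + td + ((vm + pl) if (stt >= 1 or td >= 1) else 0)
        assert total == expected
        totals.add(total)
    assert totals == set(range(11))
    # monotone: raising any single component never lowers the total
    for stt, td, vm, pl in combos:
        base = cm.total_score(stt, td, vm, pl).total
        for bump in (
            (min(stt + 1, 3), td, vm, pl), (stt, min(td + 1, 3), vm, pl),
            (stt, td, min(vm + 1, 2), pl), (stt, td, vm, min(pl + 1, 2)),
        ):
            assert cm.total_score(*bump).total >= base


def test_combined_phase_totals_reach_twenty():
    rest = cm.total_score(3, 3, 2, 2, phase="rest").total
    stress = cm.total_score(3, 3, 2, 2, phase="stress").total
    assert rest + stress == 20


@pytest.mark.parametrize("total, pathologic", [(0, False), (1, False), (2, True), (10, True)])
def test_pathologic_threshold(total, pathologic):
    assert cm.classify_pathologic(total) is pathologic
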