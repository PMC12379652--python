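"""Statistical screening, stepwise LDA, LOOCV, ROC and Box's M."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiomag as cm
from cardiomag.stats_classify import FeatureTable, PooledLDA


def enumerate_mann_whitney_p(x, y):
    """Exact two-sided p by full enumeration of group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        xs = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in rest))
    us = np.asarray(us)
    mean_u = n1 * (n - n1) / 2
    # two-sided: as or more extreme in distance from the mean
    return np.mean(np.abs(us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)


def test_mann_whitney_small_sample_example():
    u, p = cm.mann_whitney([1.0, 2.0], [3.0, 4.0])
    assert u == 0.0
    assert p == pytest.approx(1 / 3)


def test_mann_whitney_identical_samples_u_is_half_product():
    x = [1.0, 2.0, 3.0]
    u, _ = cm.mann_whitney(x, x)
    assert u == pytest.approx(len(x) ** 2 / 2)


def test_mann_whitney_extreme_shift_reaches_enumeration_minimum():
    x = [101.0, 102.0, 103.0]
    y = [1.0, 2.0, 3.0]
    _, p = cm.mann_whitney(x, y)
    assert p == pytest.approx(2 / 20)  # 2 / C(6,3)


def test_mann_whitney_empty_raises():
    with pytest.raises(ValueError):
        cm.mann_whitney([], [1.0])


def test_mann_whitney_exact_p_matches_enumeration():
    """All size pairs with n1 + n2 <= 10, tie-free random data."""
    rng = np.random.default_rng(2024)
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            if n1 + n2 > 10:
                continue
            sample = rng.normal(size=n1 + n2)
            x, y = sample[:n1], sample[n1:]
            _, p = cm.mann_whitney(x, y)
            assert p == pytest.approx(enumerate_mann_whitney_p(x, y), abs=1e-12)


# --------------------------------------------------------------- BH correction

def test_bh_single_p_unchanged():
    adj, rej = cm.benjamini_hochberg([0.04])
    assert adj[0] == pytest.approx(0.04)
    assert rej[0]


def test_bh_step_up_examples():
    adj, rej = cm.benjamini_hochberg([0.01, 0.02, 0.03], q=0.05)
    np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])
    assert rej.all()
    adj, rej = cm.benjamini_hochberg([0.04, 0.5], q=0.05)
    np.testing.assert_allclose(adj, [0.08, 0.5])
    assert not rej.any()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cm.benjamini_hochberg([0.1, 1.4])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=12), st.randoms())
def test_bh_order_invariance(pvals, rnd):
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    adj, _ = cm.benjamini_hochberg(pvals)
    adj_p, _ = cm.benjamini_hochberg([pvals[i] for i in perm])
    np.testing.assert_allclose([adj[i] for i in perm], adj_p, atol=1e-12)


# --------------------------------------------------------------- stepwise LDA

def _table(X, labels, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["label"] = labels
    return FeatureTable(df)


def test_stepwise_selects_separating_feature_first():
    rng = np.random.default_rng(0)
    n = 40
    labels = ["CAD"] * 20 + ["healthy"] * 20
    X = rng.standard_normal((n, 6))
    X[:20, 2] += 5.0  # feature 2 separates by 5 SD
    sel, model = cm.stepwise_lda(_table(X, labels))
    assert sel[0] == "f2"
    assert model is not None


def test_stepwise_respects_max_features():
    rng = np.random.default_rng(1)
    labels = ["CAD"] * 30 + ["healthy"] * 30
    X = rng.standard_normal((60, 10))
    X[:30] += 2.0  # every feature informative
    sel, _ = cm.stepwise_lda(_table(X, labels), max_features=3)
    assert len(sel) <= 3


def test_stepwise_null_calibration():
    """Identical class distributions: selection stays empty in >=90% of seeds."""
    rng = np.random.default_rng(0)
    labels = ["CAD"] * 20 + ["healthy"] * 20
    empty = 0
    for _ in range(100):
        sel, _ = cm.stepwise_lda(_table(rng.standard_normal((40, 16)), labels))
        empty += not sel
    assert empty >= 90


def test_stepwise_needs_two_per_class():
    X = np.zeros((3, 2))
    with pytest.raises(ValueError):
        cm.stepwise_lda(_table(X, ["CAD", "healthy", "healthy"]))


# --------------------------------------------------------------- LOOCV

def test_loocv_separable_classes_are_perfect():
    rng = np.random.default_rng(2)
    labels = ["CAD"] * 10 + ["healthy"] * 10
    X = rng.standard_normal((20, 2)) * 0.1
    X[:10, 0] += 10.0
    sens, spec, _ = cm.loocv_evaluate(_table(X, labels), ["f0", "f1"])
    assert sens == 1.0 and spec == 1.0


def test_loocv_chance_level_for_random_labels():
    """Label-independent features give ~50% sensitivity and specificity."""
    rng = np.random.default_rng(3)
    senss, specs = [], []
    for _ in range(50):
        labels = ["CAD"] * 30 + ["healthy"] * 30
        X = rng.standard_normal((60, 3))
        sens, spec, _ = cm.loocv_evaluate(_table(X, labels), ["f0", "f1", "f2"])
        senss.append(sens)
        specs.append(spec)
    assert abs(np.mean(senss) - 0.5) <= 0.15
    assert abs(np.mean(specs) - 0.5) <= 0.15


def test_loocv_singleton_class_raises():
    X = np.zeros((4, 1))
    X[0] = 1.0
    with pytest.raises(ValueError):
        cm.loocv_evaluate(_table(X, ["CAD", "healthy", "healthy", "healthy"]), ["f0"])


def test_pooled_lda_orients_discriminant_with_degenerate_feature():
    """A zero-within-class-variance feature still classifies correctly."""
    X = np.array([[0.0], [0.0], [2.0], [2.0]])
    y = np.array([False, False, True, True])
    model = PooledLDA().fit(X, y)
    assert not model.predict([[0.0]])[0]
    assert model.predict([[2.0]])[0]


# --------------------------------------------------------------- ROC / AUC

def test_auc_perfect_ranking():
    auc, _ = cm.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=50)
    assert auc == 1.0


def test_auc_all_ties_is_half():
    auc, _ = cm.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1], n_boot=50)
    assert auc == 0.5


def test_auc_concordance_example():
    auc, ci = cm.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=200)
    assert auc == pytest.approx(0.75)
    assert ci[0] <= auc <= ci[1]


def test_auc_antisymmetry():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]  # ensure both classes
    a1, _ = cm.roc_auc(scores, labels, n_boot=10)
    a2, _ = cm.roc_auc(-scores, labels, n_boot=10)
    assert a1 + a2 == pytest.approx(1.0)


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        cm.roc_auc([0.1, 0.2], [1, 1])


def test_auc_ci_is_deterministic_given_seed():
    scores = np.linspace(0, 1, 20)
    labels = [0, 1] * 10
    _, ci1 = cm.roc_auc(scores, labels, n_boot=200, seed=7)
    _, ci2 = cm.roc_auc(scores, labels, n_boot=200, seed=7)
    assert ci1 == ci2


# --------------------------------------------------------------- Box's M

def _cov_table(rng, n_per_class, scale_cad=1.0, p=3):
    Xh = rng.standard_normal((n_per_class, p))
    Xc = rng.standard_normal((n_per_class, p)) * scale_cad
    X = np.vstack([Xc, Xh])
    return _table(X, ["CAD"] * n_per_class + ["healthy"] * n_per_class)


def test_boxs_m_null_calibration():
    """Equal covariances: p > 0.05 in >= 90% of seeded replicates."""
    rng = np.random.default_rng(0)
    ok = sum(cm.boxs_m(_cov_table(rng, 100), ["f0", "f1", "f2"])[1] > 0.05
             for _ in range(100))
    assert ok >= 90


def test_boxs_m_detects_variance_inflation():
    rng = np.random.default_rng(1)
    _, p = cm.boxs_m(_cov_table(rng, 100, scale_cad=np.sqrt(10)), ["f0", "f1", "f2"])
    assert p < 0.01


def test_boxs_m_more_features_than_subjects_raises():
    rng = np.random.default_rng(2)
    table = _cov_table(rng, 3, p=4)
    with pytest.raises(ValueError):
        cm.boxs_m(table, ["f0", "f1", "f2", "f3"])


# --------------------------------------------------------------- FeatureTable

def test_feature_table_validates_labels():
    df = pd.DataFrame({"f0": [1.0, 2.0], "label": ["CAD", "sick"]})
    with pytest.raises(ValueError):
        FeatureTable(df)
    with pytest.raises(ValueError):
        FeatureTable(pd.DataFrame({"f0": [1.0]}))
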