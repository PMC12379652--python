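"""Group comparison and classification.

Mann-Whitney screening with Benjamini-Hochberg false-discovery-rate
correction, forward stepwise linear discriminant analysis (Wilks'-lambda
partial F entry criterion), leave-one-out cross-validation, ROC/AUC with a
stratified bootstrap confidence interval, and Box's M homoscedasticity
check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "mann_whitney",
    "benjamini_hochberg",
    "screen_features",
    "stepwise_lda",
    "loocv_evaluate",
    "roc_auc",
    "boxs_m",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
]

POSITIVE_LABEL = "CAD"
NEGATIVE_LABEL = "healthy"


@dataclass
class FeatureTable:
    """Per-subject feature matrix with a binary class label.

    ``label`` values must be 'CAD' (positive) or 'healthy' (negative).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if "label" not in self.frame.columns:
            raise ValueError("feature table needs a 'label' column")
        bad = set(self.frame["label"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.frame["label"].isna().any():
            raise ValueError("missing labels are not allowed")

    @property
    def feature_names(self) -> list[str]:
        drop = {"label", "subject"}
        return [c for c in self.frame.columns
                if c not in drop
                and pd.api.types.is_numeric_dtype(self.frame[c])
                and not pd.api.types.is_bool_dtype(self.frame[c])]

    def xy(self, features: list[str] | None = None):
        feats = features if features is not None else self.feature_names
        X = self.frame[feats].to_numpy(dtype=float)
        y = (self.frame["label"] == POSITIVE_LABEL).to_numpy()
        return X, y


@dataclass
class ClassifierReport:
    """Stepwise-LDA model summary with LOOCV performance."""

    selected_features: list[str]
    loocv_sensitivity: float
    loocv_specificity: float
    auc: float
    auc_ci: tuple[float, float]
    scores: np.ndarray
    labels: np.ndarray
    screening: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "loocv_sensitivity": self.loocv_sensitivity,
            "loocv_specificity": self.loocv_specificity,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
        }


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p-value by enumeration when n1+n2 <= 12 and the pooled sample has
    no ties; otherwise the normal approximation with tie correction (and
    continuity correction).  Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (adjusted p-values in input order, boolean rejection flags at
    level ``q``).
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)) or np.any(~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adj, reject


def screen_features(table: FeatureTable, q: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney per feature, BH-corrected across features.

    One row per feature: U, raw p, BH-adjusted p, rejection flag at ``q``,
    and the per-class means (direction of the group difference).
    """
    pos = table.frame[table.frame["label"] == POSITIVE_LABEL]
    neg = table.frame[table.frame["label"] == NEGATIVE_LABEL]
    rows = []
    for f in table.feature_names:
        u, p = mann_whitney(pos[f].to_numpy(), neg[f].to_numpy())
        rows.append({"feature": f, "U": u, "p": p,
                     "mean_cad": float(pos[f].mean()),
                     "mean_healthy": float(neg[f].mean())})
    out = pd.DataFrame(rows)
    adj, rej = benjamini_hochberg(out["p"].to_numpy(), q)
    out["p_adj"] = adj
    out["significant"] = rej
    return out


class PooledLDA:
    """Two-class linear discriminant with pooled covariance and equal priors.

    The pooled within-class covariance receives a small ridge
    (1e-8 * trace, with an absolute floor) so that a feature with zero
    within-class scatter — e.g. a discrete score that separates the classes
    perfectly — still yields a finite, correctly-oriented discriminant.
    Decision threshold is posterior 0.5 (decision function 0).
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PooledLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        mu1, mu0 = X[y].mean(axis=0), X[~y].mean(axis=0)
        p = X.shape[1]
        S = np.zeros((p, p))
        for g in (True, False):
            Xg = X[y == g] - X[y == g].mean(axis=0)
            S += Xg.T @ Xg
        S /= max(len(y) - 2, 1)
        S += (1e-8 * np.trace(S) + 1e-12) * np.eye(p)
        self.coef_ = np.linalg.solve(S, mu1 - mu0)
        self.intercept_ = -0.5 * float(self.coef_ @ (mu1 + mu0))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0


def _lda() -> PooledLDA:
    return PooledLDA()


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for a two-group design."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (True, False):
        Xg = X[y == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    ridge = 1e-12 * max(np.trace(T), 1.0) * np.eye(T.shape[0])
    sign_t, logdet_t = np.linalg.slogdet(T + ridge)
    sign_w, logdet_w = np.linalg.slogdet(W + ridge)
    if sign_t <= 0 or sign_w <= 0:
        return 1.0
    return float(np.exp(logdet_w - logdet_t))


def _f_to_enter(lam_before: float, lam_after: float, n: int, p_before: int,
                g: int = 2) -> tuple[float, float]:
    """Partial F statistic for adding one variable to a stepwise LDA model."""
    df2 = n - g - p_before
    if df2 <= 0 or lam_after <= 0:
        return 0.0, 1.0
    F = (lam_before / lam_after - 1.0) * df2 / (g - 1)
    p = float(scipy.stats.f.sf(F, g - 1, df2))
    return float(F), p


def stepwise_lda(table: FeatureTable, max_features: int = 3,
                 entry_p: float = 0.05, candidate_correction: bool = True):
    """Forward stepwise feature selection for a two-class LDA.

    At each step the candidate with the largest Wilks'-lambda partial
    F-to-enter is added if its entry p-value is significant at ``entry_p``;
    with ``candidate_correction`` (default) the entry level is Bonferroni
    corrected for the number of candidates examined at that step, which
    keeps the null selection rate near ``entry_p`` regardless of how many
    features are screened.  Selection stops at ``max_features`` or when no
    candidate passes.  Returns (selected feature names, fitted LDA or None).
    An empty selection is a valid (flagged) outcome, not an error.
    """
    X_all, y = table.xy()
    names = table.feature_names
    for g in (True, False):
        if (y == g).sum() < 2:
            raise ValueError("need at least 2 subjects per class")
    # standardize internally for numerical comparability
    mu, sd = X_all.mean(axis=0), X_all.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X_all - mu) / sd
    n = len(y)
    selected: list[int] = []
    lam_current = 1.0
    while len(selected) < max_features:
        remaining = [j for j in range(len(names)) if j not in selected]
        if not remaining:
            break
        best = None
        for j in remaining:
            cols = selected + [j]
            lam = _wilks_lambda(Xs[:, cols], y)
            F, p = _f_to_enter(lam_current, lam, n, len(selected))
            if best is None or F > best[1]:
                best = (j, F, p, lam)
        j, F, p, lam = best
        alpha = entry_p / len(remaining) if candidate_correction else entry_p
        if p >= alpha:
            break
        selected.append(j)
        lam_current = lam
    feats = [names[j] for j in selected]
    if not feats:
        return feats, None
    model = _lda()
    model.fit(X_all[:, selected], y)
    return feats, model


def loocv_evaluate(table: FeatureTable, features: list[str],
                   reselect: bool = False, max_features: int = 3,
                   entry_p: float = 0.05):
    """Leave-one-out cross-validated sensitivity and specificity.

    Each subject is predicted by an LDA refit on the remaining n-1 (equal
    priors, posterior 0.5 threshold).  With ``reselect`` the stepwise
    selection is re-run inside every fold (the conservative protocol);
    the default freezes the supplied feature set, mirroring how such
    models are usually reported (optimistic with respect to selection).
    Returns (sensitivity, specificity, per-subject decision scores).
    """
    frame = table.frame.reset_index(drop=True)
    n = len(frame)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    y = (frame["label"] == POSITIVE_LABEL).to_numpy()
    scores = np.empty(n)
    preds = np.empty(n, dtype=bool)
    for i in range(n):
        train = frame.drop(index=i)
        if train["label"].nunique() < 2:
            raise ValueError("a LOOCV fold has a single-class training set")
        sub = FeatureTable(train)
        feats = features
        if reselect:
            feats, _ = stepwise_lda(sub, max_features=max_features, entry_p=entry_p)
        if not feats:
            # no discriminative evidence in this fold: coin-flip at chance
            scores[i] = 0.0
            preds[i] = False
            continue
        Xtr, ytr = sub.xy(feats)
        model = _lda()
        model.fit(Xtr, ytr)
        xte = frame.loc[[i], feats].to_numpy(dtype=float)
        scores[i] = float(model.decision_function(xte)[0])
        preds[i] = bool(model.predict(xte)[0])
    tp = np.sum(preds & y)
    fn = np.sum(~preds & y)
    tn = np.sum(~preds & ~y)
    fp = np.sum(preds & ~y)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(sens), float(spec), scores


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 20250825,
            ci: float = 0.95):
    """AUC by pairwise concordance (ties get half credit) with bootstrap CI.

    The confidence interval is a stratified bootstrap (resampling within
    each class) percentile interval; default 2000 resamples, fixed seed.
    Returns (auc, (lo, hi)).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        boots[b] = roc_auc_score(labels[idx], scores[idx])
    a = (1 - ci) / 2
    lo, hi = np.quantile(boots, [a, 1 - a])
    return auc, (float(lo), float(hi))


def boxs_m(table: FeatureTable, features: list[str]) -> tuple[float, float]:
    """Box's M test of equal class covariance matrices (chi2 approximation).

    Returns (M statistic, approximate p-value).  Requires more subjects per
    class than features.
    """
    import pingouin

    p = len(features)
    for lab in (POSITIVE_LABEL, NEGATIVE_LABEL):
        n_g = (table.frame["label"] == lab).sum()
        if n_g <= p:
            raise ValueError("each class needs more subjects than features")
    df = table.frame[features + ["label"]].copy()
    covs = [np.cov(df[df["label"] == lab][features].to_numpy(), rowvar=False)
            for lab in (POSITIVE_LABEL, NEGATIVE_LABEL)]
    for c in covs:
        c = np.atleast_2d(c)
        if np.linalg.matrix_rank(c) < p:
            raise np.linalg.LinAlgError("singular within-class covariance")
    res = pingouin.box_m(df, dvs=features, group="label")
    return float(res["Chi2"].iloc[0]), float(res["pval"].iloc[0])
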