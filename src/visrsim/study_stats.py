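"""Classifier construction and study statistics.

Logistic regression on E/B feature subsets (fit in-sample, as the clinical
analysis appears to do), ROC/AUC via the Mann-Whitney rank statistic with the
Youden-optimal operating point, Pearson/Spearman correlations, and two-sided
Wilcoxon rank-sum comparisons (exact for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODALITIES = ("pd", "re", "rv")
FEATURE_SETS = (("pd",), ("re",), ("rv",), ("pd", "re"), ("pd", "rv"),
                ("re", "rv"), ("pd", "re", "rv"))


@dataclass
class LogisticModel:
    intercept: float                  # on standardized features
    coef: np.ndarray
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_iter: int
    converged: bool
    ridge: float

    @property
    def coef_original(self) -> np.ndarray:
        return self.coef / self.x_scale

    @property
    def intercept_original(self) -> float:
        return self.intercept - float(np.sum(self.coef * self.x_mean
                                             / self.x_scale))

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.intercept + Xs @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 feature_names: tuple[str, ...] | None = None,
                 ridge: float = 1e-6, max_iter: int = 100,
                 tol: float = 1e-10) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS on standardized features.

    A small ridge penalty (excluding the intercept) keeps the solve bounded
    under complete separation.  Deterministic for fixed input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.size > X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    if np.bincount(y.astype(int)).min() < 2:
        raise ValueError("need >= 2 rows per class")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xs = (X - x_mean) / x_scale
    A = np.column_stack([np.ones(len(y)), Xs])
    beta = np.zeros(A.shape[1])
    pen = np.full(A.shape[1], ridge)
    pen[0] = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        H = (A * w[:, None]).T @ A + np.diag(pen)
        grad = A.T @ (y - p) - pen * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"x{i}" for i in range(X.shape[1]))
    return LogisticModel(intercept=float(beta[0]), coef=beta[1:],
                         feature_names=names, x_mean=x_mean, x_scale=x_scale,
                         n_iter=it, converged=converged, ridge=ridge)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float       # at the Youden-optimal threshold
    specificity: float
    youden_threshold: float
    n: int
    degenerate: bool = False


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC as the tie-corrected Mann-Whitney concordance of the scores.

    The operating point maximizes Youden's J = sensitivity + specificity - 1;
    among ties the most specific point is reported.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    if np.all(s == s[0]):
        return ROCResult(auc=0.5, fpr=np.array([0.0, 1.0]),
                         tpr=np.array([0.0, 1.0]),
                         thresholds=np.array([np.inf, s[0]]),
                         sensitivity=1.0, specificity=0.0,
                         youden_threshold=s[0], n=len(s), degenerate=True)
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-s, kind="stable")
    s_ord, y_ord = s[order], y[order]
    distinct = np.nonzero(np.diff(s_ord))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y_ord)[idx]
    fps = np.cumsum(1 - y_ord)[idx]
    tpr = np.concatenate([[0.0], tps / n1])
    fpr = np.concatenate([[0.0], fps / n0])
    thr = np.concatenate([[np.inf], s_ord[idx]])
    j = tpr - fpr
    best = int(np.argmax(j))      # first occurrence: fewest false positives
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr,
                     sensitivity=float(tpr[best]),
                     specificity=float(1 - fpr[best]),
                     youden_threshold=float(thr[best]), n=len(s))


def correlate(x: np.ndarray, y: np.ndarray,
              method: str = "pearson") -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in input '{name}'")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact when n1+n2 <= 10 and tie-free,
    normal approximation with tie and continuity correction otherwise.
    Returns (rank-sum statistic W of the first sample, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)
    return w, float(res.pvalue)


def build_feature_table(records: pd.DataFrame,
                        modalities: tuple[str, ...]) -> pd.DataFrame:
    """Pivot E/B records to one row per lesion view; drop rows with any
    unsure member of the requested modality subset."""
    req = {"lesion_id", "rotation_deg", "modality", "eb", "unsure", "label"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    sub = records[records["modality"].isin(modalities)]
    wide = sub.pivot_table(index=["lesion_id", "rotation_deg", "label"],
                           columns="modality", values="eb",
                           aggfunc="first")
    bad = sub[sub["unsure"]].set_index(["lesion_id", "rotation_deg"]).index
    wide = wide.reset_index()
    keep = ~wide.set_index(["lesion_id", "rotation_deg"]).index.isin(set(bad))
    wide = wide[keep].dropna(subset=list(modalities))
    return wide.reset_index(drop=True)


def model_roc_for_subset(records: pd.DataFrame,
                         modalities: tuple[str, ...],
                         ridge: float = 1e-6
                         ) -> tuple[LogisticModel, ROCResult]:
    """In-sample logistic + ROC for one E/B feature subset."""
    table = build_feature_table(records, modalities)
    y = (table["label"] == "malignant").to_numpy().astype(int)
    X = table[list(modalities)].to_numpy()
    model = fit_logistic(X, y, feature_names=modalities, ridge=ridge)
    scores = model.decision(X)
    return model, roc_analysis(scores, y)
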