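"""Marker-panel selection, SVM classification and ROC evaluation.

The classifier is an RBF-kernel support vector machine over the selected
panel's natural-log-transformed, standardized projected intensities.
Training includes replicates of the urine sample pools labeled by their
source class (case pool -> positive; non-AKI and normal pools ->
negative), which stabilizes the decision boundary against technical
variance.  The decision score is the SVM's signed decision value (higher =
more AKI-like); a sample is called positive when its score exceeds the
cutoff (study convention: -0.05).

Panel selection: features significant on the Wilcoxon rank-sum test are
ranked by the combined rank of p-value and pool-replicate CV, then added
greedily; a candidate is kept only when the leave-one-out cross-validated
AUC does not drop by more than a small tolerance.

Evaluation: LOOCV scoring, empirical ROC with DeLong AUC confidence
intervals and a z-test of the AUC against 0.5, confusion counts at the
score cutoff, pool-replicate repeatability rates, a logistic-regression
combiner of two classifier scores with Youden-index thresholding, and
Kruskal-Wallis subgroup confounding checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

from .io import POOL_GROUPS
from .stats import round_half_up

__all__ = [
    "DEFAULT_CUTOFF",
    "MarkerPanel",
    "TrainedClassifier",
    "RocSummary",
    "ln_transform",
    "labels_to_binary",
    "select_panel",
    "train_svm",
    "loocv_scores",
    "loocv_roc",
    "roc_summary",
    "delong_variance",
    "confusion_at_cutoff",
    "repeatability_report",
    "combine_logistic",
    "subgroup_score_analysis",
]

#: Decision-score threshold: score > cutoff calls AKI-positive.
DEFAULT_CUTOFF = -0.05

#: Amplitude pre-scale inside the log transform.  Projected values are
#: TIC-normalized (order 1e-4..1e-3); the pre-scale puts detected values
#: well above the +1 offset that keeps non-detected zeros finite.
LN_PRESCALE = 1.0e4


def ln_transform(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """ln(1 + a*x) feature transform; zeros (non-detected) map to 0."""
    return np.log1p(LN_PRESCALE * values)


def labels_to_binary(groups: pd.Series) -> np.ndarray:
    """Map group labels to classifier targets: AKI / AKI-pool -> 1, else 0."""
    return groups.isin(["AKI", "AKI-pool"]).to_numpy().astype(int)


@dataclass
class MarkerPanel:
    """Ordered selected features with their selection trace."""

    feature_ids: list
    candidate_ids: list = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass
class TrainedClassifier:
    """SVM panel model with its standardization constants and cutoff."""

    panel: MarkerPanel
    svm: SVC
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def _design(self, dense_values: pd.DataFrame) -> np.ndarray:
        X = ln_transform(dense_values[self.panel.feature_ids].to_numpy(dtype=float))
        return (X - self.feat_mean) / self.feat_sd

    def decision_scores(self, dense_values: pd.DataFrame) -> np.ndarray:
        """Signed decision values; higher = more AKI-like."""
        return self.svm.decision_function(self._design(dense_values))

    def predict(self, dense_values: pd.DataFrame) -> np.ndarray:
        return (self.decision_scores(dense_values) > self.cutoff).astype(int)

    def to_json(self) -> str:
        """Versioned JSON serialization of the fitted model."""
        svm = self.svm
        payload = {
            "format_version": 1,
            "panel_feature_ids": [str(f) for f in self.panel.feature_ids],
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "cutoff": self.cutoff,
            "svm": {
                "kernel": svm.kernel,
                "C": svm.C,
                "gamma": float(svm.gamma),
                "support_vectors": svm.support_vectors_.tolist(),
                "dual_coef": svm.dual_coef_.tolist(),
                "intercept": svm.intercept_.tolist(),
            },
        }
        return json.dumps(payload, indent=1)


@dataclass
class RocSummary:
    """ROC of a score vector against binary labels."""

    auc: float
    ci_low: float
    ci_high: float
    p_vs_random: float
    sensitivity: float
    specificity: float
    cutoff: float
    points: pd.DataFrame = field(repr=False)
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of scores for labels==1 over labels==0."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes to compute an AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong's estimator: (AUC, variance of the AUC).

    Uses the structural-component (placement value) formulation: V10 for
    positives against the negative distribution, V01 for negatives against
    the positive distribution.
    """
    pos = np.asarray(scores)[labels == 1]
    neg = np.asarray(scores)[labels == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives (midrank for ties)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_summary(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> RocSummary:
    """Empirical ROC with DeLong 95% CI and a z-test of AUC against 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, var = delong_variance(scores, labels)
    se = np.sqrt(var)
    if se > 0:
        ci_low = max(0.0, auc - 1.959963984540054 * se)
        ci_high = min(1.0, auc + 1.959963984540054 * se)
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        ci_low = ci_high = auc
        p = 1.0 if auc == 0.5 else 0.0

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    tpr = [np.sum(scores[labels == 1] > t) / n_pos for t in thresholds]
    fpr = [np.sum(scores[labels == 0] > t) / n_neg for t in thresholds]
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})

    sens, spec, _ = confusion_at_cutoff(scores, labels, cutoff)
    return RocSummary(auc, float(ci_low), float(ci_high), p, sens, spec,
                      cutoff, points, scores, labels)


def confusion_at_cutoff(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[float, float, dict]:
    """Sensitivity/specificity (integer percent) at a decision-score cutoff.

    Positive call = score strictly above the cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("need both classes for a confusion table")
    calls = scores > cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    sens = round_half_up(100.0 * tp / (tp + fn), 0)
    spec = round_half_up(100.0 * tn / (tn + fp), 0)
    return sens, spec, {"tp": tp, "fn": fn, "tn": tn, "fp": fp}


def train_svm(
    dense_values: pd.DataFrame,
    groups: pd.Series,
    panel: MarkerPanel,
    include_pools: bool = True,
    C: float = 1.0,
    kernel: str = "rbf",
    cutoff: float = DEFAULT_CUTOFF,
) -> TrainedClassifier:
    """Fit the panel SVM on ln-transformed, standardized amplitudes.

    ``dense_values`` must have absences materialized as 0.  Pool
    replicates are retained as training points with their source-class
    label unless ``include_pools`` is False.  Standardization constants
    come from the training rows only.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    missing = [f for f in panel.feature_ids if f not in dense_values.columns]
    if missing:
        raise ValueError(f"panel feature(s) absent from matrix: {missing[:3]}")
    groups = groups.reindex(dense_values.index)
    keep = np.ones(len(dense_values), dtype=bool)
    if not include_pools:
        keep = ~groups.isin(POOL_GROUPS).to_numpy()
    X_raw = ln_transform(
        dense_values.loc[keep, panel.feature_ids].to_numpy(dtype=float)
    )
    y = labels_to_binary(groups[keep])
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    mean = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X_raw - mean) / sd
    gamma = 1.0 / len(panel)
    svm = SVC(kernel=kernel, C=C, gamma=gamma)
    svm.fit(X, y)
    return TrainedClassifier(panel, svm, mean, sd, cutoff)


def loocv_scores(
    dense_values: pd.DataFrame,
    groups: pd.Series,
    panel: MarkerPanel,
    include_pools: bool = True,
    C: float = 1.0,
    kernel: str = "rbf",
) -> pd.Series:
    """Leave-one-out decision scores.

    Each sample is scored by a model trained on all other samples.  When
    ``include_pools`` is False pool replicates stay in every training fold
    but are not scored.  Results are independent of row order.
    """
    groups = groups.reindex(dense_values.index)
    is_pool = groups.isin(POOL_GROUPS).to_numpy()
    score_mask = np.ones(len(dense_values), dtype=bool)
    if not include_pools:
        score_mask = ~is_pool

    out = {}
    for i, sid in enumerate(dense_values.index):
        if not score_mask[i]:
            continue
        train_idx = np.arange(len(dense_values)) != i
        clf = train_svm(
            dense_values.iloc[train_idx], groups.iloc[train_idx], panel,
            include_pools=True, C=C, kernel=kernel,
        )
        out[sid] = float(clf.decision_scores(dense_values.iloc[[i]])[0])
    return pd.Series(out, name="loocv_score")


def loocv_roc(
    dense_values: pd.DataFrame,
    groups: pd.Series,
    panel: MarkerPanel,
    include_pools: bool = True,
    cutoff: float = DEFAULT_CUTOFF,
    C: float = 1.0,
    kernel: str = "rbf",
) -> RocSummary:
    """ROC over leave-one-out decision scores."""
    scores = loocv_scores(dense_values, groups, panel, include_pools, C, kernel)
    y = labels_to_binary(groups.reindex(scores.index))
    if len(set(y)) < 2:
        raise ValueError("held-out scores cover only one class")
    return roc_summary(scores.to_numpy(), y, cutoff)


def select_panel(
    stats: pd.DataFrame,
    dense_values: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    target_size: int | None = None,
    auc_tolerance: float = 0.001,
    C: float = 1.0,
    kernel: str = "rbf",
) -> MarkerPanel:
    """Greedy forward panel selection under LOOCV.

    Candidates are the features with Wilcoxon p below ``alpha``, ranked by
    the combined rank of (p ascending, pool CV ascending; undefined CVs
    rank last).  Walking down the ranking, a candidate is kept iff the
    panel's mean LOOCV AUC does not decrease by more than
    ``auc_tolerance``.  Stops at ``target_size`` or candidate exhaustion.
    """
    sig = stats[stats["p_value"] < alpha]
    if sig.empty:
        raise ValueError("empty candidate pool: no feature significant at alpha")
    rank_p = sig["p_value"].rank(method="average")
    cv = sig["pool_cv"] if "pool_cv" in sig else pd.Series(np.nan, index=sig.index)
    cv = cv.replace([np.inf, -np.inf], np.nan)
    rank_cv = cv.rank(method="average", na_option="bottom")
    combined = (rank_p + rank_cv).to_frame("rank")
    combined["p"] = sig["p_value"]
    ranked = combined.sort_values(["rank", "p"]).index.tolist()

    panel_feats: list = []
    trace: list[dict] = []
    best_auc = -np.inf
    for fid in ranked:
        trial = MarkerPanel(panel_feats + [fid])
        scores = loocv_scores(dense_values, groups, trial, True, C, kernel)
        y = labels_to_binary(groups.reindex(scores.index))
        auc = _rank_auc(scores.to_numpy(), y)
        kept = auc >= best_auc - auc_tolerance
        trace.append({"feature_id": fid, "loocv_auc": auc, "kept": bool(kept)})
        if kept:
            panel_feats.append(fid)
            best_auc = max(best_auc, auc) if np.isfinite(best_auc) else auc
        if target_size is not None and len(panel_feats) >= target_size:
            break
    return MarkerPanel(panel_feats, candidate_ids=ranked, trace=trace)


def repeatability_report(
    pool_scores: pd.DataFrame,
    case_pools: list[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Misclassification rates of repeated pool analyses over time.

    ``pool_scores``: one column per pool (rows = time points, NaN =
    not analyzed that week).  Columns named in ``case_pools`` are expected
    to score positive; all others negative.  Rates are integer percents of
    misclassified replicates.
    """
    if len(pool_scores) < 2:
        warnings.warn("repeatability over a single time point is not informative",
                      stacklevel=2)
    fp = fn = n_ctrl = n_case = 0
    series = {}
    for col in pool_scores.columns:
        vals = pool_scores[col].dropna()
        positive = vals > cutoff
        series[col] = vals
        if col in case_pools:
            n_case += len(vals)
            fn += int((~positive).sum())
        else:
            n_ctrl += len(vals)
            fp += int(positive.sum())
    return {
        "series": series,
        "false_positive_rate": round_half_up(100.0 * fp / n_ctrl, 0) if n_ctrl else float("nan"),
        "false_negative_rate": round_half_up(100.0 * fn / n_case, 0) if n_case else float("nan"),
        "n_control_replicates": n_ctrl,
        "n_case_replicates": n_case,
    }


def combine_logistic(
    score_a: np.ndarray,
    score_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[object, RocSummary, float]:
    """Combine two classifier scores by two-covariate logistic regression.

    Returns the fitted model, the ROC of the combined probability score,
    and the Youden-index threshold (the observed probability maximizing
    sensitivity + specificity - 1).  On perfect separation the fit falls
    back to an L2-penalized logistic regression (flagged via warning).
    """
    import statsmodels.api as sm

    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y)) < 2:
        raise ValueError("labels are constant; cannot fit a classifier combiner")
    X = sm.add_constant(np.column_stack([a, b]))
    prob = None
    model: object
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sps.ConstantInputWarning)
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.all(np.isfinite(fit.bse)) or np.abs(fit.params).max() > 1e3:
            raise sps.ConstantInputWarning("separation suspected")
        prob = np.asarray(fit.predict(X))
        model = fit
    except Exception:
        from sklearn.linear_model import LogisticRegression

        warnings.warn("perfect separation: falling back to penalized logistic fit",
                      stacklevel=2)
        lr = LogisticRegression(C=1.0)
        lr.fit(np.column_stack([a, b]), y)
        prob = lr.predict_proba(np.column_stack([a, b]))[:, 1]
        model = lr

    # Youden threshold over the observed combined scores
    best_t, best_j = prob.min(), -np.inf
    for t in np.unique(prob):
        sens = np.mean(prob[y == 1] >= t)
        spec = np.mean(prob[y == 0] < t)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    # ROC cutoff convention is score > t; use just-below the Youden score
    roc = roc_summary(prob, y, cutoff=best_t - 1e-12)
    return model, roc, best_t


def subgroup_score_analysis(
    scores: np.ndarray,
    subgroup_labels: np.ndarray | pd.Series,
) -> float:
    """Kruskal-Wallis p-value for score differences across subgroups.

    Used to check that the decision score is not confounded by, e.g.,
    sepsis severity or AKI stage.  Subgroups with no members are dropped
    with a warning; with exactly two subgroups this reduces to the
    Wilcoxon rank-sum test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(subgroup_labels)
    groups = []
    for lab in pd.unique(labels):
        vals = scores[labels == lab]
        if vals.size == 0:
            warnings.warn(f"subgroup {lab!r} has no members; dropped", stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty subgroups")
    return float(sps.kruskal(*groups).pvalue)
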