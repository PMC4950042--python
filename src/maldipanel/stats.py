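"""Per-feature case/control marker statistics.

Group differences are scored with the two-sided Wilcoxon rank-sum test and
its companion Mann-Whitney AUC.  Non-detected samples enter as amplitude 0
(ties at the bottom of the ranking), so a feature can discriminate through
its detection frequency as well as its amplitude.  Rank statistics are
invariant under strictly increasing transforms, so the natural-log
transform applied before classification changes neither p nor AUC.

Pool-replicate variability: markers are preferred when their amplitude is
stable across repeated analyses of the urine sample pools; the score is
the coefficient of variation per pool type, averaged over pool types.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureMatrix
from .io import PATIENT_GROUPS, POOL_GROUPS

__all__ = [
    "wilcoxon_feature",
    "group_summaries",
    "pool_variability",
    "fold_change",
    "round_half_up",
]

#: group sizes at or below which the exact permutation null is enumerated
EXACT_MAX_N = 8


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed clinical tables)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(numer: float, denom: float, ndigits: int = 2) -> float:
    """Case/control ratio rounded half-up; NaN when the denominator is 0."""
    if denom == 0:
        return float("nan")
    return round_half_up(numer / denom, ndigits)


def _mannwhitney_u(case: np.ndarray, control: np.ndarray) -> tuple[float, np.ndarray]:
    """U statistic for the case group, with midrank tie handling."""
    pooled = np.concatenate([case, control])
    ranks = sps.rankdata(pooled)
    n1 = case.size
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return float(u1), ranks


def wilcoxon_feature(
    case_values: np.ndarray | list[float],
    control_values: np.ndarray | list[float],
    oriented: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p-value and Mann-Whitney AUC.

    AUC = U/(n1*n2) computed in (case, control) order: values above 0.5
    mean cases rank higher.  With ``oriented`` (reporting parity with
    published marker tables) the returned AUC is ``max(auc, 1-auc)``.

    The null is enumerated exactly over all group assignments of the
    pooled values when both groups have at most 8 observations (correct
    under ties); otherwise the tie-corrected normal approximation is used
    (for two groups this coincides with the Kruskal-Wallis chi-square).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one value")
    n1, n2 = case.size, control.size
    u1, ranks = _mannwhitney_u(case, control)
    auc = u1 / (n1 * n2)

    mu = n1 * n2 / 2.0
    if np.ptp(np.concatenate([case, control])) == 0:
        p = 1.0
    elif n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # exact permutation null of U over all C(n1+n2, n1) assignments
        n = n1 + n2
        idx = np.array(list(combinations(range(n), n1)), dtype=int)
        r1_all = ranks[idx].sum(axis=1)
        u_all = r1_all - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u1 - mu) - 1e-12))
    else:
        pooled = np.concatenate([case, control])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u1 - mu) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if oriented:
        auc = max(auc, 1.0 - auc)
    return p, float(auc)


def pool_variability(matrix: FeatureMatrix) -> pd.Series:
    """Per-feature CV of projected amplitude across pool replicates.

    Within each pool type with at least two replicates: CV = sample SD /
    mean of the replicate values (zeros for non-detected replicates
    included); the feature's score is the mean CV over pool types.
    Features undetected in more than half of all pool replicates get +inf
    (too unreliable to score).  With fewer than two pool replicates in
    total, all CVs are undefined (NaN).
    """
    is_pool = matrix.groups.isin(POOL_GROUPS)
    n_pool = int(is_pool.sum())
    if n_pool < 2:
        return pd.Series(np.nan, index=matrix.values.columns, name="pool_cv")

    pool_vals = matrix.values.loc[is_pool.values]
    detected_frac = pool_vals.notna().mean(axis=0)

    cvs = []
    for ptype in POOL_GROUPS:
        sel = (matrix.groups == ptype)
        if int(sel.sum()) < 2:
            continue
        v = matrix.values.loc[sel.values].fillna(0.0)
        mean = v.mean(axis=0)
        sd = v.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvs.append((sd / mean).replace([np.inf, -np.inf], np.nan))
    if not cvs:
        return pd.Series(np.nan, index=matrix.values.columns, name="pool_cv")
    cv = pd.concat(cvs, axis=1).mean(axis=1)
    cv[detected_frac < 0.5] = np.inf
    cv.name = "pool_cv"
    return cv


def group_summaries(
    matrix: FeatureMatrix,
    patient_groups: tuple[str, str] = PATIENT_GROUPS,
) -> pd.DataFrame:
    """Marker statistics table, one row per feature.

    Means and SDs are over the patient groups' projected amplitudes with
    zeros included for non-detected samples; frequencies are the detected
    fractions; fold changes are case/control ratios of means and of
    frequencies, rounded half-up to 2 decimals for reporting (NaN when the
    control denominator is zero).  ``auc`` is max-oriented for reporting
    parity; ``auc_signed`` preserves the (case, control) orientation.
    """
    case_sel = matrix.groups == patient_groups[0]
    ctrl_sel = matrix.groups == patient_groups[1]
    if not case_sel.any() or not ctrl_sel.any():
        raise ValueError("both patient groups must be present in the matrix")

    dense = matrix.values.fillna(0.0)
    case = dense.loc[case_sel.values]
    ctrl = dense.loc[ctrl_sel.values]
    case_det = matrix.values.loc[case_sel.values].notna()
    ctrl_det = matrix.values.loc[ctrl_sel.values].notna()
    pool_cv = pool_variability(matrix)

    rows = []
    for fid in matrix.values.columns:
        cv_case = case[fid].to_numpy()
        cv_ctrl = ctrl[fid].to_numpy()
        p, auc = wilcoxon_feature(cv_case, cv_ctrl, oriented=True)
        _, auc_signed = wilcoxon_feature(cv_case, cv_ctrl, oriented=False)
        c_mean, c_sd = float(cv_case.mean()), float(cv_case.std(ddof=1))
        n_mean, n_sd = float(cv_ctrl.mean()), float(cv_ctrl.std(ddof=1))
        c_freq = float(case_det[fid].mean())
        n_freq = float(ctrl_det[fid].mean())
        rows.append(
            {
                "feature_id": fid,
                "consensus_mz": float(matrix.feature_info.loc[fid, "consensus_mz"]),
                "p_value": p,
                "auc": auc,
                "auc_signed": auc_signed,
                "case_mean": c_mean,
                "case_sd": c_sd,
                "case_freq": c_freq,
                "control_mean": n_mean,
                "control_sd": n_sd,
                "control_freq": n_freq,
                "fc_amplitude": fold_change(c_mean, n_mean),
                "fc_frequency": fold_change(c_freq, n_freq),
                "pool_cv": float(pool_cv.get(fid, np.nan)),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
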