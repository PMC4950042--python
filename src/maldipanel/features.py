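"""Consensus feature binning and frequency filtering across the cohort.

Per-sample quantified peptides are consolidated into cohort-wide feature
bins by single-linkage m/z chaining (break at gaps larger than the bin
tolerance), restricted to the instrument's usable peptide mass window.
Each bin carries its consensus mass (intensity-weighted mean of member
masses) and per-sample projected intensity; undetected entries are
structural absences (NaN), materialized as 0 only when exporting for
classifier input.  Two detection-frequency gates then mirror the study's
filtering: features seen in more than 10% of all samples, then more than
25% in at least one of the two patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PATIENT_GROUPS
from .quantify import QuantifiedSample, _cluster_slices

__all__ = ["FeatureMatrix", "bin_features", "frequency_filter"]


@dataclass
class FeatureMatrix:
    """Samples x consensus-feature matrix of projected intensities.

    ``values``: DataFrame indexed by sample_id with feature_id columns;
    NaN = feature not detected in that sample.  ``feature_info``: per
    feature, consensus m/z and the SD of member masses.  ``groups``:
    group label per sample.
    """

    values: pd.DataFrame
    feature_info: pd.DataFrame
    groups: pd.Series = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def detection_frequency(self) -> pd.Series:
        """Fraction of all samples in which each feature is detected."""
        return self.values.notna().mean(axis=0)

    def group_frequency(self, group: str) -> pd.Series:
        sel = self.groups == group
        if not sel.any():
            return pd.Series(0.0, index=self.values.columns)
        return self.values.loc[sel.values].notna().mean(axis=0)

    def dense(self, fill: float = 0.0) -> pd.DataFrame:
        """Materialized matrix with absences as ``fill`` (classifier input)."""
        return self.values.fillna(fill)

    def subset(self, feature_ids: list) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[feature_ids],
            self.feature_info.loc[feature_ids],
            self.groups,
        )


def bin_features(
    quantified: list[QuantifiedSample],
    bin_tol: float = 0.1,
    mass_window: tuple[float, float] = (800.0, 3100.0),
    groups: pd.Series | None = None,
) -> FeatureMatrix:
    """Pool all passed peptides of all samples and chain them into bins.

    All peaks are globally sorted by m/z before chaining, so the result is
    invariant to sample input order.  If one sample contributes several
    peaks to a bin, the one nearest the consensus mass is kept.
    """
    if bin_tol <= 0:
        raise ValueError("bin_tol must be positive")
    if not quantified:
        raise ValueError("need at least one quantified sample")

    sample_ids = [q.sample_id for q in quantified]
    rows = []
    for q in quantified:
        for p in q.passed_peptides():
            rows.append((p.mz, p.projected_value, q.sample_id))
    if not rows:
        raise ValueError("no passed peptides to bin")

    mz = np.array([r[0] for r in rows])
    val = np.array([r[1] for r in rows])
    sid = np.array([r[2] for r in rows], dtype=object)
    order = np.argsort(mz, kind="stable")
    mz, val, sid = mz[order], val[order], sid[order]

    lo, hi = mass_window
    feature_cols = {}
    info_rows = []
    fid = 0
    for sl in _cluster_slices(mz, bin_tol):
        c_mz, c_val, c_sid = mz[sl], val[sl], sid[sl]
        consensus = float(np.average(c_mz, weights=c_val if c_val.sum() > 0 else None))
        if not (lo <= consensus <= hi):
            continue
        # one value per sample: nearest to consensus mass
        if np.unique(c_sid).size != c_sid.size:
            keep = np.zeros(c_sid.size, dtype=bool)
            for s in np.unique(c_sid):
                idx = np.flatnonzero(c_sid == s)
                keep[idx[np.argmin(np.abs(c_mz[idx] - consensus))]] = True
            c_mz, c_val, c_sid = c_mz[keep], c_val[keep], c_sid[keep]
        col = pd.Series(c_val, index=c_sid)
        feature_cols[fid] = col
        info_rows.append(
            {
                "feature_id": fid,
                "consensus_mz": consensus,
                "mz_sd": float(c_mz.std(ddof=1)) if c_mz.size > 1 else 0.0,
                "n_members": int(c_mz.size),
            }
        )
        fid += 1

    values = pd.DataFrame(feature_cols, index=sample_ids)
    values.columns.name = "feature_id"
    info = pd.DataFrame(info_rows).set_index("feature_id")
    if groups is None:
        groups = pd.Series("", index=values.index, name="group")
    else:
        groups = groups.reindex(values.index)
    return FeatureMatrix(values, info, groups)


def frequency_filter(
    matrix: FeatureMatrix,
    overall_min: float = 0.10,
    group_min: float = 0.25,
    patient_groups: tuple[str, str] = PATIENT_GROUPS,
) -> FeatureMatrix:
    """Apply the two detection-frequency gates (strict inequalities).

    First keep features detected in more than ``overall_min`` of all
    samples; then keep those detected in more than ``group_min`` of at
    least one of the two patient groups (pool replicates count toward the
    overall gate but not the group gate).  Idempotent.
    """
    for thr in (overall_min, group_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("frequency thresholds must be in [0, 1]")
    overall = matrix.detection_frequency()
    keep = overall > overall_min
    ga = matrix.group_frequency(patient_groups[0])
    gb = matrix.group_frequency(patient_groups[1])
    keep &= (ga > group_min) | (gb > group_min)
    kept = list(matrix.values.columns[keep])
    return matrix.subset(kept)
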