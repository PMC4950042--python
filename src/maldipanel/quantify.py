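"""Dilution-series quantification of spot peak lists.

Because MALDI intensity response leaves the linear range at high analyte
load and no internal standard is spotted, relative quantification is done
by regression over a 12-step serial dilution: for every peptide of every
sample, TIC-normalized intensities of the replicate-merged dilution spots
are fitted by a line in log-log coordinates and the fitted intensity is
*projected to dilution factor 1* (the most concentrated spot).  Gross
outlier points are pruned iteratively by their perpendicular distance from
the refitted line in variance-standardized coordinates; series observed at
fewer than three dilutions, or whose final slope is not negative
(intensity failing to fall with dilution — saturation or artifact), are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SampleManifest, SpotPeakList

__all__ = [
    "QuantifyParams",
    "PeptideQuant",
    "QuantifiedSample",
    "normalize_spot",
    "merge_replicates",
    "pruning_distances",
    "fit_dilution_regression",
    "quantify_sample",
    "quantify_cohort",
]

#: uL-equivalents of the reference (most concentrated) spot; dilution
#: factor = this / dilution_equiv, so the least-dilute spot has factor 1.
REFERENCE_DILUTION_EQUIV = 0.35


@dataclass
class QuantifyParams:
    """Tunable gates of the quantification stage.

    min_observed_replicates: a merged peak needs this many of the (up to 4)
    technical replicates.  min_dilutions_observed: a series needs this many
    merged dilution points to be fitted at all.  min_points: pruning never
    reduces a series below this many points.  max_perp_dist: pruning
    threshold in sigmas of the residual scatter (see pruning_distances).
    """

    mz_tol: float = 0.1
    min_observed_replicates: int = 3
    min_dilutions_observed: int = 3
    min_points: int = 6
    max_perp_dist: float = 2.0


@dataclass
class PeptideQuant:
    """Quantification result for one peptide series within one sample."""

    mz: float
    projected_value: float | None
    slope: float | None
    points_used: int
    points_removed: int
    passed: bool
    reason: str | None = None


@dataclass
class QuantifiedSample:
    sample_id: str
    peptides: list[PeptideQuant] = field(default_factory=list)

    def passed_peptides(self) -> list[PeptideQuant]:
        return [p for p in self.peptides if p.passed]


def normalize_spot(spot: SpotPeakList) -> SpotPeakList:
    """Total-ion-current normalization: divide by the spot's summed intensity."""
    total = spot.total_intensity()
    if total <= 0:
        raise ValueError(f"spot {spot.spot_id!r}: zero total intensity")
    return SpotPeakList(spot.spot_id, spot.mz.copy(), spot.intensity / total)


def _cluster_by_gap(mz_sorted: np.ndarray, tol: float) -> np.ndarray:
    """Single-linkage chaining: break whenever adjacent sorted masses gap > tol.

    Returns an integer cluster label per (sorted) entry.
    """
    if mz_sorted.size == 0:
        return np.array([], dtype=int)
    breaks = np.diff(mz_sorted) > tol
    return np.concatenate([[0], np.cumsum(breaks)])


def _cluster_slices(mz_sorted: np.ndarray, tol: float) -> list[slice]:
    """Contiguous index ranges of the gap-chained clusters."""
    if mz_sorted.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(mz_sorted) > tol) + 1
    bounds = np.concatenate([[0], cuts, [mz_sorted.size]])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def merge_replicates(
    spots: list[SpotPeakList],
    min_observed: int = 3,
    mz_tol: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine technical replicate spots measured at one dilution.

    Peaks are matched across replicates by single-linkage m/z chaining with
    tolerance ``mz_tol``; a merged peak is emitted only when observed in at
    least ``min_observed`` replicates (at most one peak per replicate per
    cluster).  Merged intensity is the mean over observed replicates;
    merged m/z is the intensity-weighted mean (stronger peaks centroid more
    precisely).

    Returns (mz, intensity, n_observed) arrays sorted by m/z.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    if not spots:
        return np.array([]), np.array([]), np.array([], dtype=int)
    min_observed = min(min_observed, len(spots))

    mz = np.concatenate([s.mz for s in spots])
    inten = np.concatenate([s.intensity for s in spots])
    rep = np.concatenate([np.full(s.n_peaks, i) for i, s in enumerate(spots)])
    order = np.argsort(mz, kind="stable")
    mz, inten, rep = mz[order], inten[order], rep[order]

    out_mz, out_int, out_n = [], [], []
    for sl in _cluster_slices(mz, mz_tol):
        c_mz, c_int, c_rep = mz[sl], inten[sl], rep[sl]
        # at most one peak per replicate: keep the one nearest the cluster median
        if np.unique(c_rep).size != c_rep.size:
            med = np.median(c_mz)
            keep = np.zeros(c_rep.size, dtype=bool)
            for r in np.unique(c_rep):
                idx = np.flatnonzero(c_rep == r)
                keep[idx[np.argmin(np.abs(c_mz[idx] - med))]] = True
            c_mz, c_int, c_rep = c_mz[keep], c_int[keep], c_rep[keep]
        if c_rep.size < min_observed:
            continue
        w = c_int if c_int.sum() > 0 else np.ones_like(c_int)
        out_mz.append(float(np.average(c_mz, weights=w)))
        out_int.append(float(c_int.mean()))
        out_n.append(int(c_rep.size))
    return np.array(out_mz), np.array(out_int), np.array(out_n, dtype=int)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _standardized_perp_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point from the OLS line, after
    standardizing both coordinates to zero mean / unit variance."""
    sx = x.std() or 1.0
    sy = y.std() or 1.0
    xs = (x - x.mean()) / sx
    ys = (y - y.mean()) / sy
    b, a = _ols(xs, ys)
    return np.abs(ys - (a + b * xs)) / np.sqrt(1.0 + b * b)


def pruning_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Outlier score per point: perpendicular distance from the refitted
    line in standardized coordinates, expressed in units of the RMS
    distance of the current points (so the pruning threshold is a number
    of sigmas of the residual scatter).  All-zero when the points are
    colinear to numerical precision."""
    d = _standardized_perp_distances(x, y)
    rms = float(np.sqrt(np.mean(d * d)))
    if rms < 1e-9:
        return np.zeros_like(d)
    return d / rms


def fit_dilution_regression(
    dilution_equiv: np.ndarray,
    intensity: np.ndarray,
    params: QuantifyParams | None = None,
    mz: float = float("nan"),
) -> PeptideQuant:
    """Fit one peptide's dilution series and project to dilution factor 1.

    Coordinates: x = log10(dilution factor), with factor =
    ``REFERENCE_DILUTION_EQUIV / dilution_equiv`` so the most concentrated
    spot sits at x = 0; y = log10(merged normalized intensity).  After
    iterative pruning (remove the single worst point while its RMS-scaled
    perpendicular distance exceeds ``max_perp_dist`` and more than
    ``min_points`` remain, refitting each step), the series passes iff it
    started with at least ``min_dilutions_observed`` points and the final
    slope is negative; the projected value is 10**intercept.

    Pruning is deterministic: among equal distances the point with the
    lower dilution factor is removed first.
    """
    params = params or QuantifyParams()
    equiv = np.asarray(dilution_equiv, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if equiv.size != inten.size or equiv.size == 0:
        raise ValueError("dilution series must be non-empty and aligned")
    factors = REFERENCE_DILUTION_EQUIV / equiv
    # canonical order: increasing dilution factor (breaks distance ties)
    order = np.argsort(factors, kind="stable")
    x = np.log10(factors[order])
    y = np.log10(np.clip(inten[order], 1e-300, None))

    if x.size < params.min_dilutions_observed:
        return PeptideQuant(mz, None, None, int(x.size), 0, False, "insufficient dilutions")

    removed = 0
    while x.size > max(params.min_points, 2):
        d = pruning_distances(x, y)
        worst = int(np.argmax(d))  # argmax → first (lowest factor) among ties
        if d[worst] <= params.max_perp_dist:
            break
        x = np.delete(x, worst)
        y = np.delete(y, worst)
        removed += 1

    slope, intercept = _ols(x, y)
    if slope >= 0:
        return PeptideQuant(mz, None, slope, int(x.size), removed, False, "non-negative slope")
    return PeptideQuant(mz, float(10.0 ** intercept), slope, int(x.size), removed, True)


def quantify_sample(
    spots: list[SpotPeakList],
    manifest: SampleManifest,
    sample_id: str,
    params: QuantifyParams | None = None,
) -> QuantifiedSample:
    """Normalize, merge and regress every peptide of one sample.

    ``spots`` may contain the whole cohort; the manifest selects this
    sample's spots.  Peptide series are linked across dilutions by the same
    m/z chaining used within dilutions.
    """
    params = params or QuantifyParams()
    sub = manifest.spots_of(sample_id)
    by_id = {s.spot_id: s for s in spots}

    # merge replicates per dilution level
    merged_mz, merged_int, merged_equiv = [], [], []
    for equiv, rows in sub.groupby("dilution_equiv"):
        level_spots = []
        for sid in rows["spot_id"]:
            if sid in by_id:
                level_spots.append(normalize_spot(by_id[sid]))
        if not level_spots:
            continue
        m_mz, m_int, _ = merge_replicates(
            level_spots, params.min_observed_replicates, params.mz_tol
        )
        merged_mz.append(m_mz)
        merged_int.append(m_int)
        merged_equiv.append(np.full(m_mz.size, equiv))

    result = QuantifiedSample(sample_id)
    if not merged_mz:
        return result
    mz = np.concatenate(merged_mz)
    inten = np.concatenate(merged_int)
    equiv = np.concatenate(merged_equiv)
    if mz.size == 0:
        return result

    order = np.argsort(mz, kind="stable")
    mz, inten, equiv = mz[order], inten[order], equiv[order]
    for sl in _cluster_slices(mz, params.mz_tol):
        c_mz, c_int, c_equiv = mz[sl], inten[sl], equiv[sl]
        # one point per dilution level: keep the peak nearest the series median m/z
        if np.unique(c_equiv).size != c_equiv.size:
            med = np.median(c_mz)
            keep = np.zeros(c_equiv.size, dtype=bool)
            for e in np.unique(c_equiv):
                idx = np.flatnonzero(c_equiv == e)
                keep[idx[np.argmin(np.abs(c_mz[idx] - med))]] = True
            c_mz, c_int, c_equiv = c_mz[keep], c_int[keep], c_equiv[keep]
        series_mz = float(np.average(c_mz, weights=c_int if c_int.sum() > 0 else None))
        result.peptides.append(
            fit_dilution_regression(c_equiv, c_int, params, mz=series_mz)
        )
    return result


def quantify_cohort(
    spots: list[SpotPeakList],
    manifest: SampleManifest,
    params: QuantifyParams | None = None,
) -> list[QuantifiedSample]:
    """Quantify every sample named in the manifest."""
    by_sample: dict[str, list[SpotPeakList]] = {}
    spot_to_sample = dict(
        zip(manifest.table["spot_id"], manifest.table["sample_id"])
    )
    for s in spots:
        sid = spot_to_sample.get(s.spot_id)
        if sid is not None:
            by_sample.setdefault(sid, []).append(s)
    return [
        quantify_sample(by_sample.get(sid, []), manifest, sid, params)
        for sid in manifest.sample_ids
    ]
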