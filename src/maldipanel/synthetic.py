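"""Ground-truthed synthetic MALDI cohort generator.

Emulates the study design end to end: individual AKI case and non-AKI
control urine samples plus three repeatedly analyzed urine pools (normal,
AKI, non-AKI), each measured as a 12-step serial dilution spotted in
quadruplicate.  Per-peptide amplitude distributions (group mean, SD and
detection frequency, zeros included) default to the published statistics
of the 39-peptide AKI marker panel; non-marker "background" peptides with
identical group distributions are added to exercise selection specificity.

Amplitude model
---------------
For each (sample, peptide): the peptide is present with probability equal
to its group detection frequency; if present, its true amplitude (the
projected, TIC-normalized intensity at dilution factor 1, up to the fixed
TIC scale) is drawn from a log-normal whose two moments are matched so
that the *zero-inflated* distribution reproduces the configured
including-zeros mean and SD.  Intensities are positive and right-skewed,
and for many reported peptides the SD exceeds the mean, which the
log-normal accommodates.

Spot model
----------
The raw peak intensity of a present peptide at dilution factor f is
``min(a / f, saturation) * (1 + eps)`` with multiplicative Gaussian noise
of CV ``noise_cv``, occasional gross outliers (x10 or x0.1), and a
logistic drop-out probability in log10(f) mimicking loss of low-abundance
peaks at high dilution.  Every spot also carries a fixed set of
matrix/chemical background peaks that absorb the remainder of a constant
total ion current: with more analyte the matrix signal is suppressed, so
the spot TIC is constant — the idealization that makes TIC normalization
exactly invertible and lets noise-free series be exactly linear through
the origin in dilution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SampleManifest, SpotPeakList
from .reference import PeptideParams, reference_marker_params

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "default_dilution_series",
    "generate_cohort",
    "generate_amplitude_matrix",
    "make_background_params",
]

#: Fixed spot total ion current (arbitrary counts).  Peptide signal is a
#: few percent of this at the most concentrated spot; the matrix peaks
#: absorb the rest.
SPOT_TIC = 1.0e6

#: Reference (least dilute) spot volume in uL-equivalents of urine.
REFERENCE_DILUTION_EQUIV = 0.35


def default_dilution_series(n: int = 12) -> np.ndarray:
    """12 uL-equivalent volumes log-spaced over two orders of magnitude."""
    return np.geomspace(0.35, 0.0035, n)


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults are the published study conditions: 17 cases + 17 controls,
    4 replicates each of the three urine pools (12 pool samples), 12-step
    dilution series in quadruplicate, and the 39-peptide reference panel
    plus 200 null background peptides.
    """

    n_case: int = 17
    n_control: int = 17
    n_pool_replicates: int = 4  # per pool type (3 types)
    peptide_params: list[PeptideParams] = field(default_factory=reference_marker_params)
    n_background: int = 200
    dilution_series: np.ndarray = field(default_factory=default_dilution_series)
    saturation_level: float | None = None  # raw counts; None = no clipping
    noise_cv: float = 0.1
    outlier_rate: float = 0.05
    # detection probability at dilution factor f: sigmoid((midpoint - log10 f)/scale)
    dropout_midpoint: float = 1.5
    dropout_scale: float = 0.3
    mz_jitter_sd: float = 0.02  # Da, per spot
    n_replicates: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required: generation must be reproducible")
        dil = np.asarray(self.dilution_series, dtype=float)
        if np.any(np.diff(dil) >= 0):
            raise ValueError("dilution_series must be strictly decreasing")
        self.dilution_series = dil
        for p in self.peptide_params:
            if not (0.0 <= p.case_freq <= 1.0 and 0.0 <= p.control_freq <= 1.0):
                raise ValueError(f"peptide {p.peptide_id}: frequencies must be in [0,1]")
            if min(p.case_mean, p.case_sd, p.control_mean, p.control_sd) < 0:
                raise ValueError(f"peptide {p.peptide_id}: means/SDs must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth: per-sample projected amplitudes at dilution factor 1.

    ``amplitudes`` is samples x peptides on the TIC-normalized scale (raw
    amplitude divided by the constant spot TIC); 0 = peptide absent from
    that sample.  ``is_marker`` flags the group-differential peptides.
    ``outliers`` lists the (spot_id, mz) points whose intensity received a
    gross multiplicative error.
    """

    amplitudes: pd.DataFrame
    peptide_mz: np.ndarray
    is_marker: np.ndarray
    groups: pd.Series
    outliers: list[tuple[str, float]]


def make_background_params(
    n: int,
    marker_mz: np.ndarray,
    rng: np.random.Generator,
    mean: float = 600.0,
    sd: float = 600.0,
    freq: float = 0.5,
    mz_range: tuple[float, float] = (800.0, 3100.0),
    min_spacing: float = 0.5,
) -> list[PeptideParams]:
    """Null peptides with identical case/control distributions.

    Masses are drawn uniformly over the instrument's peptide range, kept at
    least ``min_spacing`` Da from every marker mass and from each other so
    consensus binning cannot merge distinct species.
    """
    taken = list(np.asarray(marker_mz, dtype=float))
    out: list[PeptideParams] = []
    next_id = 100000
    while len(out) < n:
        mz = float(rng.uniform(*mz_range))
        if any(abs(mz - t) < min_spacing for t in taken):
            continue
        taken.append(mz)
        out.append(
            PeptideParams(
                peptide_id=next_id + len(out), mz=mz,
                case_mean=mean, case_sd=sd, case_freq=freq,
                control_mean=mean, control_sd=sd, control_freq=freq,
            )
        )
    return out


def _lognormal_moments(mean: float, sd: float, freq: float) -> tuple[float, float]:
    """(mu, sigma) of the conditional-on-detection log-normal.

    The configured mean/SD include zeros; with detection probability q the
    detected-amplitude moments are m_d = mean/q and
    E[A^2] = (sd^2 + mean^2)/q.  If the implied conditional variance is not
    positive (possible for extreme printed rounding), fall back to a 30% CV.
    """
    q = max(freq, 1e-12)
    m_d = mean / q
    ex2 = (sd * sd + mean * mean) / q
    var_d = ex2 - m_d * m_d
    if var_d <= 0:
        var_d = (0.3 * m_d) ** 2
    sigma2 = np.log1p(var_d / (m_d * m_d))
    mu = np.log(m_d) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _draw_sample_amplitudes(
    params: list[PeptideParams], is_case: bool, rng: np.random.Generator
) -> np.ndarray:
    """Raw-scale amplitudes for one individual (0 where not detected)."""
    amps = np.zeros(len(params))
    for k, p in enumerate(params):
        mean, sd, freq = (
            (p.case_mean, p.case_sd, p.case_freq)
            if is_case
            else (p.control_mean, p.control_sd, p.control_freq)
        )
        if mean <= 0 or freq <= 0:
            continue
        if rng.random() < freq:
            mu, sigma = _lognormal_moments(mean, sd, freq)
            amps[k] = rng.lognormal(mu, sigma)
    return amps


# fixed chemical-noise mass ladder shared by all spots: matrix clusters and
# unresolved chemical background across the acquisition window
def _matrix_background_mz(rng: np.random.Generator, n: int = 60) -> tuple[np.ndarray, np.ndarray]:
    mz = np.sort(rng.uniform(805.0, 3095.0, n))
    weights = rng.dirichlet(np.full(n, 2.0))
    return mz, weights


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SpotPeakList], SampleManifest, SyntheticTruth]:
    """Generate spot peak lists, manifest and ground truth for one cohort.

    Sample ids are ``case01..``, ``ctrl01..``, ``pool-normal-r1..``,
    ``pool-AKI-r1..``, ``pool-nonAKI-r1..``; spot ids encode sample,
    dilution step and replicate.  Pool amplitudes are the per-peptide mean
    (zeros included) of their member individuals' true amplitudes; the
    normal pool is built from unobserved healthy donors drawn from the
    control distribution.
    """
    rng = np.random.default_rng(config.seed)
    marker_params = list(config.peptide_params)
    marker_mz = np.array([p.mz for p in marker_params])
    background = make_background_params(config.n_background, marker_mz, rng)
    params = marker_params + background
    pep_mz = np.array([p.mz for p in params])
    is_marker = np.array([k < len(marker_params) for k in range(len(params))])

    # --- sample-level truth ------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    amplitudes: list[np.ndarray] = []

    case_amps, ctrl_amps = [], []
    for i in range(config.n_case):
        a = _draw_sample_amplitudes(params, True, rng)
        sample_ids.append(f"case{i + 1:02d}")
        groups.append("AKI")
        amplitudes.append(a)
        case_amps.append(a)
    for i in range(config.n_control):
        a = _draw_sample_amplitudes(params, False, rng)
        sample_ids.append(f"ctrl{i + 1:02d}")
        groups.append("non-AKI")
        amplitudes.append(a)
        ctrl_amps.append(a)

    # pooled urine: mean concentration over members, zeros included
    pool_truth = {}
    if config.n_pool_replicates > 0:
        n_virtual = max(config.n_control, 1)
        normal_members = [
            _draw_sample_amplitudes(params, False, rng) for _ in range(n_virtual)
        ]
        pool_truth["normal-pool"] = np.mean(normal_members, axis=0)
        pool_truth["AKI-pool"] = (
            np.mean(case_amps, axis=0) if case_amps else np.zeros(len(params))
        )
        pool_truth["nonAKI-pool"] = (
            np.mean(ctrl_amps, axis=0) if ctrl_amps else np.zeros(len(params))
        )
        for ptype, short in [("normal-pool", "normal"), ("AKI-pool", "AKI"),
                             ("nonAKI-pool", "nonAKI")]:
            for r in range(config.n_pool_replicates):
                sample_ids.append(f"pool-{short}-r{r + 1}")
                groups.append(ptype)
                amplitudes.append(pool_truth[ptype])

    amp = np.array(amplitudes)  # samples x peptides, raw scale

    # --- spot synthesis ----------------------------------------------------
    chem_mz, chem_w = _matrix_background_mz(rng)
    factors = REFERENCE_DILUTION_EQUIV / config.dilution_series
    log_f = np.log10(factors)
    p_detect_dil = 1.0 / (1.0 + np.exp((log_f - config.dropout_midpoint) / config.dropout_scale))

    spots: list[SpotPeakList] = []
    manifest_rows = []
    outliers: list[tuple[str, float]] = []
    sat = np.inf if config.saturation_level is None else config.saturation_level

    for s_idx, sid in enumerate(sample_ids):
        present = amp[s_idx] > 0
        for d_idx, (equiv, f) in enumerate(zip(config.dilution_series, factors)):
            for rep in range(1, config.n_replicates + 1):
                spot_id = f"{sid}_d{d_idx + 1:02d}_r{rep}"
                detected = present & (rng.random(len(params)) < p_detect_dil[d_idx])
                raw = np.minimum(amp[s_idx][detected] / f, sat)
                if config.noise_cv > 0:
                    raw = raw * (1.0 + config.noise_cv * rng.standard_normal(raw.size))
                    raw = np.clip(raw, 1e-9, None)
                mz_obs = pep_mz[detected]
                if config.outlier_rate > 0:
                    hit = rng.random(raw.size) < config.outlier_rate
                    fac = np.where(rng.random(raw.size) < 0.5, 0.1, 10.0)
                    raw = np.where(hit, raw * fac, raw)
                    outliers.extend((spot_id, float(m)) for m in mz_obs[hit])
                if config.mz_jitter_sd > 0:
                    mz_obs = mz_obs + config.mz_jitter_sd * rng.standard_normal(mz_obs.size)
                # matrix suppression: chemical background fills the TIC
                residual = max(SPOT_TIC - raw.sum(), 0.05 * SPOT_TIC)
                all_mz = np.concatenate([mz_obs, chem_mz])
                all_int = np.concatenate([raw, chem_w * residual])
                spots.append(SpotPeakList(spot_id, all_mz, all_int))
                manifest_rows.append(
                    {
                        "spot_id": spot_id,
                        "sample_id": sid,
                        "group": groups[s_idx],
                        "cohort_role": "train",
                        "dilution_equiv": equiv,
                        "replicate_index": rep,
                    }
                )

    manifest = SampleManifest(pd.DataFrame(manifest_rows))
    truth = SyntheticTruth(
        amplitudes=pd.DataFrame(amp / SPOT_TIC, index=sample_ids,
                                columns=[p.peptide_id for p in params]),
        peptide_mz=pep_mz,
        is_marker=is_marker,
        groups=pd.Series(groups, index=sample_ids, name="group"),
        outliers=outliers,
    )
    return spots, manifest, truth


def generate_amplitude_matrix(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Sample-level amplitude matrix without spot synthesis.

    Shortcut for statistical experiments that do not exercise the
    dilution-series quantification: returns the projected-amplitude matrix
    (samples x peptides, NaN = not detected), group labels and the
    is_marker flag vector.  Columns are peptide ids; amplitudes are on the
    TIC-normalized scale used by the full pipeline.
    """
    cfg = replace(config, noise_cv=0.0, outlier_rate=0.0)
    rng = np.random.default_rng(cfg.seed)
    marker_params = list(cfg.peptide_params)
    marker_mz = np.array([p.mz for p in marker_params])
    background = make_background_params(cfg.n_background, marker_mz, rng)
    params = marker_params + background
    is_marker = np.array([k < len(marker_params) for k in range(len(params))])

    rows, ids, groups = [], [], []
    for i in range(cfg.n_case):
        rows.append(_draw_sample_amplitudes(params, True, rng))
        ids.append(f"case{i + 1:02d}")
        groups.append("AKI")
    for i in range(cfg.n_control):
        rows.append(_draw_sample_amplitudes(params, False, rng))
        ids.append(f"ctrl{i + 1:02d}")
        groups.append("non-AKI")
    mat = np.array(rows) / SPOT_TIC
    df = pd.DataFrame(mat, index=ids, columns=[p.peptide_id for p in params])
    df = df.mask(df == 0.0)
    return df, pd.Series(groups, index=ids, name="group"), is_marker
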