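"""Published reference statistics of the 39-peptide urinary AKI marker panel.

The study that established the panel reports, for each marker peptide,
its consensus MALDI mass, Wilcoxon p-value and AUC in the training cohort,
and the per-group amplitude distribution: mean +/- SD of the projected
intensity (zeros for non-detected samples included) and the detection
frequency, separately for AKI cases and non-AKI controls.  These numbers
fully parameterize the synthetic-cohort generator and anchor the
fold-change bookkeeping, so the whole pipeline can be exercised without
the (undeposited) raw spectra.

Also included: the seven panel peptides whose amino-acid sequences were
resolved by cross-referencing CE-MS profiles against a urinary peptide
sequence database (lowercase ``p`` = hydroxyproline).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PeptideParams",
    "reference_marker_params",
    "reference_marker_table",
    "reference_sequences",
]


@dataclass(frozen=True)
class PeptideParams:
    """Per-peptide group amplitude model: mean/SD include zeros, freq in [0,1]."""

    peptide_id: int
    mz: float
    case_mean: float
    case_sd: float
    case_freq: float
    control_mean: float
    control_sd: float
    control_freq: float


# (id, mz, p, auc, case_mean, case_sd, case_freq%, ctrl_mean, ctrl_sd,
#  ctrl_freq%, fold-change amplitudes, fold-change frequencies)
_MARKER_ROWS = [
    (76, 811.097, 3.87e-2, 0.60, 570, 833, 39, 909, 1012, 60, 0.63, 0.65),
    (105, 816.548, 6.87e-3, 0.64, 711, 931, 47, 1121, 1037, 75, 0.63, 0.63),
    (214, 844.507, 2.35e-3, 0.65, 698, 878, 47, 1150, 920, 75, 0.61, 0.63),
    (273, 859.483, 2.88e-2, 0.61, 580, 746, 42, 951, 978, 63, 0.61, 0.67),
    (278, 861.026, 1.39e-2, 0.62, 650, 1071, 38, 1012, 1263, 65, 0.64, 0.58),
    (345, 878.762, 1.07e-2, 0.63, 830, 1022, 51, 1236, 956, 77, 0.67, 0.66),
    (368, 883.695, 1.99e-2, 0.62, 1072, 1125, 62, 1653, 1481, 81, 0.65, 0.77),
    (474, 917.227, 3.20e-2, 0.61, 755, 783, 55, 1069, 779, 75, 0.71, 0.73),
    (557, 950.624, 1.04e-2, 0.63, 803, 812, 53, 1214, 776, 77, 0.66, 0.69),
    (601, 969.401, 3.87e-3, 0.65, 598, 681, 46, 1001, 685, 73, 0.60, 0.63),
    (617, 975.372, 3.81e-2, 0.61, 808, 792, 55, 1093, 737, 75, 0.74, 0.73),
    (687, 1013.438, 3.22e-2, 0.61, 978, 827, 62, 1196, 619, 83, 0.82, 0.75),
    (715, 1025.931, 2.33e-4, 0.69, 715, 835, 47, 1357, 902, 81, 0.53, 0.58),
    (749, 1041.460, 2.33e-2, 0.61, 672, 720, 50, 940, 665, 69, 0.71, 0.72),
    (838, 1082.065, 2.79e-3, 0.65, 747, 816, 50, 1246, 797, 81, 0.60, 0.62),
    (862, 1094.760, 1.38e-2, 0.62, 483, 556, 46, 324, 517, 31, 1.49, 1.48),
    (937, 1131.830, 4.97e-2, 0.60, 925, 679, 70, 1124, 658, 79, 0.82, 0.89),
    (1016, 1177.712, 1.63e-3, 0.66, 535, 642, 45, 878, 651, 69, 0.61, 0.65),
    (1020, 1180.520, 2.48e-3, 0.64, 688, 715, 51, 334, 655, 23, 2.06, 2.22),
    (1077, 1212.565, 4.70e-2, 0.60, 497, 654, 39, 722, 655, 58, 0.69, 0.67),
    (1095, 1221.740, 1.92e-2, 0.61, 482, 678, 36, 769, 655, 62, 0.63, 0.58),
    (1116, 1236.580, 4.23e-2, 0.60, 405, 631, 31, 664, 793, 46, 0.61, 0.67),
    (1148, 1255.570, 1.76e-2, 0.60, 577, 622, 49, 783, 624, 67, 0.74, 0.73),
    (1149, 1255.774, 4.47e-2, 0.60, 872, 696, 64, 619, 738, 44, 1.41, 1.45),
    (1165, 1265.574, 3.30e-2, 0.61, 641, 645, 51, 813, 638, 65, 0.79, 0.78),
    (1226, 1307.620, 4.85e-2, 0.60, 640, 849, 41, 945, 872, 63, 0.68, 0.65),
    (1232, 1310.609, 6.41e-3, 0.64, 909, 691, 66, 589, 695, 44, 1.54, 1.50),
    (1237, 1315.670, 2.60e-2, 0.60, 396, 608, 31, 679, 690, 52, 0.58, 0.60),
    (1245, 1323.625, 7.46e-3, 0.63, 661, 646, 54, 357, 559, 31, 1.85, 1.74),
    (1310, 1368.637, 1.17e-3, 0.64, 639, 769, 43, 224, 509, 17, 2.85, 2.53),
    (1346, 1397.930, 6.23e-3, 0.62, 525, 634, 43, 643, 629, 54, 0.82, 0.80),
    (1374, 1423.990, 4.92e-2, 0.59, 372, 592, 30, 614, 687, 48, 0.61, 0.63),
    (1376, 1424.670, 1.49e-3, 0.64, 619, 752, 43, 215, 497, 17, 2.88, 2.53),
    (1396, 1439.606, 1.28e-2, 0.62, 755, 675, 58, 439, 628, 35, 1.72, 1.66),
    (1543, 1576.740, 1.48e-2, 0.60, 359, 566, 31, 195, 426, 19, 1.84, 1.63),
    (1544, 1577.740, 3.83e-2, 0.59, 397, 556, 36, 217, 474, 19, 1.83, 1.89),
    (1625, 1669.820, 9.00e-3, 0.61, 452, 638, 39, 191, 455, 17, 2.37, 2.29),
    (1636, 1676.785, 6.25e-4, 0.64, 632, 825, 41, 172, 467, 13, 3.67, 3.15),
    (1835, 2048.950, 1.19e-2, 0.60, 308, 542, 28, 44, 185, 6, 7.00, 4.67),
]

# (peptide_id, sequence [lowercase p = hydroxyproline], protein, aa_range,
#  published sequence-derived monoisotopic mass [Da], identifier)
_SEQUENCE_ROWS = [
    (214, "NGERIEK", "beta-2-microglobulin", "62-68", 844.440, "B2M[Asn62-Lys68]"),
    (1020, "GppGppGPAGKEG", "Collagen alpha-1(I) chain", "893-905", 1180.536, "COL1A1[Gly893-Gly905]"),
    (1095, "IGPpGPAGApGDKG", "Collagen alpha-1(I) chain", "769-782", 1221.599, "COL1A1[Ile769-Gly782]"),
    (1165, "SpGPDGKTGPpGPA", "Collagen alpha-1(I) chain", "546-559", 1265.589, "COL1A1[Ser546-Ala559]"),
    (1396, "TIDEKGTEAAGAMF", "alpha-1-antitrypsin", "363-376", 1439.660, "SERPINA1[Thr363-Phe376]"),
    (1625, "DEAGSEADHEGTHSTK", "Fibrinogen alpha chain", "605-620", 1669.682, "FGA[Asp605-Arg621]"),
    (1835, "TGPAGEpGREGSPGADGPPGRD", "Collagen alpha-1(II) chain", "1028-1049", 2048.915, "COL1A2[Thr1028-Asp1049]"),
]


def reference_marker_table() -> pd.DataFrame:
    """Full published panel statistics as a DataFrame (one row per peptide).

    Frequencies are returned as fractions in [0, 1]; ``p`` and ``auc`` are
    the published training-cohort Wilcoxon statistics; the two ``fc_*``
    columns are the published case/control fold changes of mean amplitudes
    and of detection frequencies (2-decimal).
    """
    df = pd.DataFrame(
        _MARKER_ROWS,
        columns=[
            "peptide_id", "mz", "p", "auc",
            "case_mean", "case_sd", "case_freq",
            "control_mean", "control_sd", "control_freq",
            "fc_amplitude", "fc_frequency",
        ],
    )
    df["case_freq"] = df["case_freq"] / 100.0
    df["control_freq"] = df["control_freq"] / 100.0
    return df


def reference_marker_params() -> list[PeptideParams]:
    """The 39 panel peptides as generator parameters (default marker set)."""
    return [
        PeptideParams(
            peptide_id=int(r[0]), mz=float(r[1]),
            case_mean=float(r[4]), case_sd=float(r[5]), case_freq=r[6] / 100.0,
            control_mean=float(r[7]), control_sd=float(r[8]), control_freq=r[9] / 100.0,
        )
        for r in _MARKER_ROWS
    ]


def reference_sequences() -> pd.DataFrame:
    """Sequence-identified panel peptides with their derived neutral masses."""
    return pd.DataFrame(
        _SEQUENCE_ROWS,
        columns=["peptide_id", "sequence", "protein", "aa_range",
                 "sequence_mass", "identifier"],
    )
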