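"""Peptide monoisotopic masses and mass-based feature annotation.

Urinary peptide features measured on the MALDI platform are assigned
sequences by mass matching against peptides already sequence-identified on
an orthogonal CE-MS platform.  All masses here are *neutral* monoisotopic
Da (no protonation): the CE-MS and sequence-derived reference masses are
neutral, and the instrument's own centroid masses are compared against
them with an absolute Da tolerance because centroid scatter (up to ~0.17
Da in practice) dominates over ppm-scale calibration error.

Collagen-derived urinary peptides are heavily hydroxylated; lowercase
``p`` in a sequence denotes hydroxyproline (proline + one oxygen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WATER_MONO",
    "RESIDUE_MONO",
    "monoisotopic_mass",
    "MassMatch",
    "match_masses",
    "calibration_check",
]

#: Monoisotopic mass of H2O added once per peptide chain.
WATER_MONO = 18.010565

#: Monoisotopic oxygen addition (Pro -> Hyp).
_OXYGEN = 15.994915

#: Standard amino-acid residue monoisotopic masses [Da].
RESIDUE_MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
    # hydroxyproline, written lowercase in collagen peptide sequences
    "p": 97.05276 + _OXYGEN,
}


def monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide sequence.

    Parameters
    ----------
    sequence
        One-letter residue codes; lowercase ``p`` is hydroxyproline.
        All other letters must be uppercase standard codes.

    Returns
    -------
    float
        Sum of residue masses plus one water, in Da.  Round to 3 decimals
        for parity with published sequence-derived mass tables.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MONO
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MONO[aa]
        except KeyError:
            raise ValueError(f"illegal residue symbol {aa!r} at position {i}") from None
    return total


@dataclass
class MassMatch:
    """One feature-to-target mass assignment."""

    feature_index: int
    query_mass: float
    target_index: int | None
    target_mass: float | None
    delta: float | None
    delta_ppm: float | None
    matched: bool


def match_masses(
    features: np.ndarray | list[float],
    targets: np.ndarray | list[float],
    tol_da: float = 0.2,
) -> list[MassMatch]:
    """One-to-one greedy mass matching of features against reference masses.

    Pairs are assigned in order of increasing |delta|; each feature and each
    target is used at most once; features with no target within ``tol_da``
    are returned unmatched.  Ties in |delta| go to the lower-mass feature,
    then the lower-mass target, so the result is independent of input order.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    feats = np.asarray(features, dtype=float)
    targs = np.asarray(targets, dtype=float)

    candidates = []
    for i, fm in enumerate(feats):
        for j, tm in enumerate(targs):
            delta = fm - tm
            if abs(delta) <= tol_da:
                candidates.append((abs(delta), fm, tm, i, j))
    candidates.sort()

    used_f: set[int] = set()
    used_t: set[int] = set()
    assigned: dict[int, int] = {}
    for _, _, _, i, j in candidates:
        if i in used_f or j in used_t:
            continue
        used_f.add(i)
        used_t.add(j)
        assigned[i] = j

    out = []
    for i, fm in enumerate(feats):
        if i in assigned:
            j = assigned[i]
            delta = float(fm - targs[j])
            out.append(MassMatch(i, float(fm), j, float(targs[j]), delta,
                                 delta / targs[j] * 1e6, True))
        else:
            out.append(MassMatch(i, float(fm), None, None, None, None, False))
    return out


def calibration_check(
    observed: np.ndarray | list[float],
    reference: np.ndarray | list[float],
    max_ppm: float = 10.0,
) -> pd.DataFrame:
    """Mass-accuracy check of calibrant peaks against their reference masses.

    The instrument is externally calibrated on standard peptides; the
    acceptance rule is that every calibrant deviates by at most ``max_ppm``
    parts per million.  Returns a per-pair table with a ``pass`` column;
    the check as a whole passes iff all rows pass.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference lists must have equal length")
    ppm = (obs - ref) / ref * 1e6
    return pd.DataFrame(
        {"observed": obs, "reference": ref, "ppm": ppm, "pass": np.abs(ppm) <= max_ppm}
    )
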