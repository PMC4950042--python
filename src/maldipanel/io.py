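"""Spot-level peak-list and sample-manifest I/O.

A *spot* is one position on the MALDI target plate, holding one dilution x
technical-replicate of one urine sample.  Peak lists are exported by the
instrument software as plain ``mz,intensity`` CSV, one file per spot; the
manifest links spot ids to samples, group labels, dilution levels and
replicate indices.  Masses are neutral monoisotopic Da throughout; any
[M+H]+ adjustment is the responsibility of whoever exports the peak lists.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpotPeakList",
    "SampleManifest",
    "PeakListError",
    "ManifestError",
    "GROUPS",
    "POOL_GROUPS",
    "PATIENT_GROUPS",
    "read_peaklist",
    "read_peaklists",
    "write_peaklists",
    "read_manifest",
    "write_manifest",
    "validate_spots_against_manifest",
]

#: Legal group labels.  Individual patient samples are ``AKI`` / ``non-AKI``;
#: the three urine pools are repeatedly re-analyzed for variance
#: stabilization and repeatability scoring.
PATIENT_GROUPS = ("AKI", "non-AKI")
POOL_GROUPS = ("normal-pool", "AKI-pool", "nonAKI-pool")
GROUPS = PATIENT_GROUPS + POOL_GROUPS

#: Advisory dilution range, in uL-equivalents of urine spotted.
DILUTION_RANGE = (0.0035, 0.35)

MANIFEST_COLUMNS = [
    "spot_id",
    "sample_id",
    "group",
    "cohort_role",
    "dilution_equiv",
    "replicate_index",
]


class PeakListError(ValueError):
    """Raised for malformed or invalid peak-list files."""


class ManifestError(ValueError):
    """Raised for malformed or inconsistent sample manifests."""


@dataclass
class SpotPeakList:
    """Peak list of a single target spot.

    ``mz`` is strictly increasing after construction; duplicate m/z rows
    (split centroids) are merged by intensity sum.  Intensities are raw
    detector counts (arbitrary units) until :func:`maldipanel.quantify.normalize_spot`.
    """

    spot_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.size == 0:
            raise PeakListError(f"spot {self.spot_id!r}: no peaks")
        if mz.size != inten.size:
            raise PeakListError(f"spot {self.spot_id!r}: mz/intensity length mismatch")
        if np.any(~np.isfinite(mz)) or np.any(mz <= 0):
            raise PeakListError(f"spot {self.spot_id!r}: non-positive or non-finite m/z")
        if np.any(~np.isfinite(inten)) or np.any(inten < 0):
            raise PeakListError(f"spot {self.spot_id!r}: negative or non-finite intensity")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # merge duplicate m/z rows by summing their intensities
        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        self.mz = mz
        self.intensity = inten

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SampleManifest:
    """Per-spot metadata table linking spots to samples and dilutions."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
        if df["spot_id"].duplicated().any():
            dup = df.loc[df["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise ManifestError(f"duplicate spot_id in manifest: {dup!r}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ManifestError(f"unknown group label(s): {sorted(bad_groups)}")
        rep = df["replicate_index"].astype(int)
        if ((rep < 1) | (rep > 4)).any():
            raise ManifestError("replicate_index outside 1..4")
        df = df.copy()
        df["replicate_index"] = rep
        df["dilution_equiv"] = df["dilution_equiv"].astype(float)
        if (df["dilution_equiv"] <= 0).any():
            raise ManifestError("dilution_equiv must be positive")
        lo, hi = DILUTION_RANGE
        out_of_range = df[(df["dilution_equiv"] < lo) | (df["dilution_equiv"] > hi)]
        if len(out_of_range):
            warnings.warn(
                f"{len(out_of_range)} spot(s) have dilution_equiv outside "
                f"the usual {lo}-{hi} uL-equivalent range",
                stacklevel=3,
            )
        for sid, sub in df.groupby("sample_id"):
            n_dil = sub["dilution_equiv"].nunique()
            if n_dil > 12:
                raise ManifestError(f"sample {sid!r}: more than 12 distinct dilutions")
            counts = sub.groupby("dilution_equiv")["spot_id"].count()
            if (counts > 4).any():
                raise ManifestError(f"sample {sid!r}: more than 4 replicate spots at one dilution")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    def group_of(self, sample_id: str) -> str:
        sub = self.table.loc[self.table["sample_id"] == sample_id, "group"]
        if sub.empty:
            raise ManifestError(f"sample {sample_id!r} not in manifest")
        return str(sub.iloc[0])

    def sample_groups(self) -> pd.Series:
        """Group label per sample_id (first spot's label)."""
        return self.table.groupby("sample_id", sort=False)["group"].first()

    def spots_of(self, sample_id: str) -> pd.DataFrame:
        sub = self.table[self.table["sample_id"] == sample_id]
        if sub.empty:
            raise ManifestError(f"sample {sample_id!r} not in manifest")
        return sub


def read_peaklist(path: str | Path) -> SpotPeakList:
    """Read one ``mz,intensity`` CSV peak-list file; spot_id = file stem."""
    path = Path(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "mz":
                continue
            if len(row) < 2:
                raise PeakListError(f"{path.name}:{lineno}: expected 'mz,intensity', got {row!r}")
            try:
                mz, inten = float(row[0]), float(row[1])
            except ValueError as exc:
                raise PeakListError(f"{path.name}:{lineno}: non-numeric value: {row!r}") from exc
            if inten < 0:
                raise PeakListError(f"{path.name}:{lineno}: negative intensity {inten}")
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise PeakListError(f"{path.name}: no peaks")
    return SpotPeakList(path.stem, np.array(mzs), np.array(intens))


def read_peaklists(path: str | Path) -> list[SpotPeakList]:
    """Read a directory of per-spot CSV files (or one file).

    Spots are keyed by id; the file-system enumeration order never reaches
    downstream code (results are sorted by spot_id).
    """
    path = Path(path)
    if path.is_file():
        return [read_peaklist(path)]
    files = sorted(path.glob("*.csv"))
    if not files:
        raise PeakListError(f"no .csv peak-list files under {path}")
    return [read_peaklist(f) for f in files]


def write_peaklists(spots: list[SpotPeakList], outdir: str | Path) -> None:
    """Write one ``<spot_id>.csv`` per spot with full float precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for spot in spots:
        with open(outdir / f"{spot.spot_id}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mz", "intensity"])
            for mz, inten in zip(spot.mz, spot.intensity):
                writer.writerow([repr(float(mz)), repr(float(inten))])


def read_manifest(path: str | Path) -> SampleManifest:
    """Read and validate the sample-manifest CSV."""
    df = pd.read_csv(path, dtype={"spot_id": str, "sample_id": str})
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def validate_spots_against_manifest(
    spots: list[SpotPeakList], manifest: SampleManifest
) -> None:
    """Check that every loaded spot is declared in the manifest and vice versa."""
    spot_ids = {s.spot_id for s in spots}
    manifest_ids = set(manifest.table["spot_id"])
    orphans = spot_ids - manifest_ids
    if orphans:
        raise ManifestError(
            f"{len(orphans)} spot(s) in peak lists but absent from manifest, "
            f"e.g. {sorted(orphans)[:3]}"
        )
    missing = manifest_ids - spot_ids
    if missing:
        raise ManifestError(
            f"{len(missing)} spot(s) declared in manifest but have no peak list, "
            f"e.g. {sorted(missing)[:3]}"
        )
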