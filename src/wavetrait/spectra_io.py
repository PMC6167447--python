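"""Reading, writing and preprocessing of canopy reflectance spectra.

Spectra live on a fixed 1-nm wavelength grid from 350 to 2500 nm (2151
bands), the native output grid of full-range field spectroradiometers.
Three atmospheric water-vapour absorption windows (1350-1410, 1790-1950
and 2471-2500 nm) are too noisy for canopy work; they are zeroed so the
spectrum stays continuous for the wavelet transform, and flagged in a
boolean mask so downstream feature ranking can exclude them.

Table dialects
--------------
Spectra: UTF-8 delimited text, first column ``sample_id``, remaining
columns named by integer wavelength ("350" ... "2500"), reflectance as a
fraction in [0, 1].  Traits: columns ``sample_id``, ``clb_kg_m2``,
``experiment_id``, ``site``, ``variety``, ``sampling_date``,
``growth_stage`` (``before`` / ``after`` anthesis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WL_MIN",
    "WL_MAX",
    "N_BANDS",
    "WAVELENGTHS",
    "WATER_WINDOWS",
    "water_band_mask",
    "SpectralSample",
    "TraitRecord",
    "Dataset",
    "SpectraIOError",
    "apply_water_band_mask",
    "assign_split",
    "read_spectra_table",
    "write_spectra_table",
    "read_trait_table",
    "write_trait_table",
]

WL_MIN = 350
WL_MAX = 2500
N_BANDS = WL_MAX - WL_MIN + 1  # 2151
WAVELENGTHS = np.arange(WL_MIN, WL_MAX + 1)

#: Closed wavelength intervals (nm) dominated by atmospheric water absorption.
WATER_WINDOWS = ((1350, 1410), (1790, 1950), (2471, 2500))


class SpectraIOError(ValueError):
    """Malformed spectral or trait table."""


def water_band_mask() -> np.ndarray:
    """Boolean mask over the canonical grid, True inside a water window."""
    mask = np.zeros(N_BANDS, dtype=bool)
    for lo, hi in WATER_WINDOWS:
        mask[(WAVELENGTHS >= lo) & (WAVELENGTHS <= hi)] = True
    return mask


_WATER_MASK = water_band_mask()


@dataclass
class SpectralSample:
    """One canopy reflectance spectrum on the canonical 1-nm grid.

    Parameters
    ----------
    sample_id : str
        Opaque sample identifier.
    reflectance : ndarray, shape (2151,)
        Reflectance fraction per band, in [0, 1].
    mask : ndarray of bool, shape (2151,)
        True where the band sits inside an excluded water window.  Masked
        bands carry reflectance exactly 0.0.
    """

    sample_id: str
    reflectance: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: np.zeros(N_BANDS, bool))

    @property
    def wavelengths(self) -> np.ndarray:
        return WAVELENGTHS

    def validate(self) -> None:
        r = np.asarray(self.reflectance, float)
        if r.shape != (N_BANDS,):
            raise SpectraIOError(
                f"sample {self.sample_id!r}: expected {N_BANDS} bands, got {r.shape}"
            )
        if not np.all(np.isfinite(r[~self.mask])):
            bad = WAVELENGTHS[~np.isfinite(np.where(self.mask, 0.0, r))][:1]
            raise SpectraIOError(
                f"sample {self.sample_id!r}: non-finite reflectance at {bad} nm"
            )
        unmasked = r[~self.mask]
        if unmasked.size and (unmasked.min() < 0.0 or unmasked.max() > 1.0):
            idx = np.where((r < 0.0) | (r > 1.0))[0]
            idx = idx[~self.mask[idx]]
            wl = int(WAVELENGTHS[idx[0]])
            raise SpectraIOError(
                f"sample {self.sample_id!r}: reflectance {r[idx[0]]:g} at "
                f"{wl} nm outside [0, 1]"
            )
        if np.any(r[self.mask] != 0.0):
            raise SpectraIOError(
                f"sample {self.sample_id!r}: masked band with nonzero reflectance"
            )


@dataclass
class TraitRecord:
    """Ground-truth trait and grouping metadata for one sample.

    ``clb`` is canopy leaf biomass in kg dry weight per m^2 (strictly
    positive).  The remaining fields are the grouping variables used for
    subgroup stability reports.
    """

    sample_id: str
    clb: float
    experiment_id: str
    site: str = ""
    variety: str = ""
    sampling_date: str = ""
    growth_stage: str = "before"

    def validate(self) -> None:
        if not (self.clb > 0 and np.isfinite(self.clb)):
            raise SpectraIOError(
                f"sample {self.sample_id!r}: clb must be finite and > 0, "
                f"got {self.clb!r}"
            )

    @property
    def year(self) -> str:
        return str(self.sampling_date)[:4]


@dataclass
class Dataset:
    """Joined spectra + traits with an experiment-level split assignment."""

    samples: list[SpectralSample]
    traits: list[TraitRecord]
    #: per sample_id: "calibration" | "validation"
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sids = [s.sample_id for s in self.samples]
        tids = [t.sample_id for t in self.traits]
        if sorted(sids) != sorted(tids):
            raise SpectraIOError("sample_ids of spectra and traits do not join 1:1")
        if len(set(sids)) != len(sids):
            raise SpectraIOError("duplicate sample_ids in dataset")
        self._by_id = {t.sample_id: t for t in self.traits}

    def __len__(self) -> int:
        return len(self.samples)

    def trait_of(self, sample_id: str) -> TraitRecord:
        return self._by_id[sample_id]

    def subset(self, role: str) -> "Dataset":
        """Return the calibration or validation part as a new Dataset."""
        keep = {sid for sid, r in self.split.items() if r == role}
        return Dataset(
            samples=[s for s in self.samples if s.sample_id in keep],
            traits=[t for t in self.traits if t.sample_id in keep],
            split={sid: role for sid in keep},
        )

    def to_arrays(self, role: str | None = None):
        """(ids, reflectance matrix (n, 2151), clb vector, metadata frame)."""
        samples = self.samples
        if role is not None:
            keep = {sid for sid, r in self.split.items() if r == role}
            samples = [s for s in samples if s.sample_id in keep]
        ids = [s.sample_id for s in samples]
        refl = np.stack([s.reflectance for s in samples]) if samples else \
            np.empty((0, N_BANDS))
        traits = [self._by_id[i] for i in ids]
        clb = np.array([t.clb for t in traits])
        meta = pd.DataFrame(
            {
                "sample_id": ids,
                "experiment_id": [t.experiment_id for t in traits],
                "site": [t.site for t in traits],
                "variety": [t.variety for t in traits],
                "sampling_date": [t.sampling_date for t in traits],
                "growth_stage": [t.growth_stage for t in traits],
                "year": [t.year for t in traits],
            }
        )
        return ids, refl, clb, meta


def apply_water_band_mask(sample: SpectralSample) -> SpectralSample:
    """Zero the three water-absorption windows and set the mask flags.

    Idempotent; all bands outside the closed windows are left untouched.
    """
    refl = np.array(sample.reflectance, dtype=float, copy=True)
    refl[_WATER_MASK] = 0.0
    return replace(sample, reflectance=refl, mask=_WATER_MASK.copy())


def assign_split(dataset: Dataset, calibration_experiments: Iterable[str]) -> Dataset:
    """Label whole experiments calibration, everything else validation.

    The split is assigned at the experiment level only, so samples of one
    experiment are never separated between the two roles.
    """
    cal = set(calibration_experiments)
    known = {t.experiment_id for t in dataset.traits}
    unknown = cal - known
    if unknown:
        raise SpectraIOError(f"unknown experiment id(s): {sorted(unknown)}")
    split = {
        t.sample_id: ("calibration" if t.experiment_id in cal else "validation")
        for t in dataset.traits
    }
    return Dataset(samples=dataset.samples, traits=dataset.traits, split=split)


def read_spectra_table(path: str | Path) -> list[SpectralSample]:
    """Read a wide spectra table; returns unmasked samples on the grid.

    Band columns are reordered to the canonical grid if needed.  Missing
    bands, non-numeric cells and duplicate ids raise :class:`SpectraIOError`
    naming the offending row/column.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise SpectraIOError(f"{path}: first column must be 'sample_id'")
    band_cols = {}
    for c in df.columns[1:]:
        try:
            band_cols[int(c)] = c
        except ValueError as exc:
            raise SpectraIOError(f"{path}: non-wavelength column {c!r}") from exc
    missing = [w for w in WAVELENGTHS if w not in band_cols]
    if missing:
        raise SpectraIOError(f"{path}: missing band(s) {missing[:5]} nm")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise SpectraIOError(f"{path}: duplicate sample_id {dup!r}")
    ordered = df[[band_cols[int(w)] for w in WAVELENGTHS]]
    try:
        values = ordered.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectraIOError(f"{path}: non-numeric reflectance cell ({exc})") from exc
    samples = []
    for sid, row in zip(ids, values):
        s = SpectralSample(sample_id=sid, reflectance=row)
        s.validate()
        samples.append(s)
    return samples


def write_spectra_table(samples: Sequence[SpectralSample], path: str | Path) -> None:
    df = pd.DataFrame(
        np.stack([s.reflectance for s in samples]),
        columns=[str(w) for w in WAVELENGTHS],
    )
    df.insert(0, "sample_id", [s.sample_id for s in samples])
    df.to_csv(path, index=False, float_format="%.12g")


_TRAIT_COLS = [
    "sample_id",
    "clb_kg_m2",
    "experiment_id",
    "site",
    "variety",
    "sampling_date",
    "growth_stage",
]


def read_trait_table(path: str | Path) -> list[TraitRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _TRAIT_COLS if c not in df.columns]
    if missing:
        raise SpectraIOError(f"{path}: missing trait column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            clb = float(row["clb_kg_m2"])
        except ValueError as exc:
            raise SpectraIOError(
                f"{path}: non-numeric clb for sample {row['sample_id']!r}"
            ) from exc
        rec = TraitRecord(
            sample_id=str(row["sample_id"]),
            clb=clb,
            experiment_id=str(row["experiment_id"]),
            site=str(row["site"]),
            variety=str(row["variety"]),
            sampling_date=str(row["sampling_date"]),
            growth_stage=str(row["growth_stage"]),
        )
        rec.validate()
        records.append(rec)
    return records


def write_trait_table(traits: Sequence[TraitRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in traits],
            "clb_kg_m2": [t.clb for t in traits],
            "experiment_id": [t.experiment_id for t in traits],
            "site": [t.site for t in traits],
            "variety": [t.variety for t in traits],
            "sampling_date": [t.sampling_date for t in traits],
            "growth_stage": [t.growth_stage for t in traits],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
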