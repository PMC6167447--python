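"""Correlation-scalogram screening of wavelet features.

For one mother wavelet, a simple linear regression of the trait on the
wavelet coefficient is evaluated at every (wavelength, scale) cell of the
calibration set; the resulting matrix of calibration R^2 values is the
correlation scalogram.  The best cells (top q, default 1%) form the
candidate feature set of that function.  Aggregating the top sets of many
functions gives an occurrence map; summarising each function by its best
eligible R^2 and applying the 1.5 IQR box-plot outlier rule ranks the
mother wavelets into optimal / ordinary / poor.

Cells inside the zeroed water windows, and cells flagged as dependent on
the zero padding at the spectrum boundaries, are computed and exported
but ineligible for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .cwt_engine import DEFAULT_SCALE_EXPONENTS, cwt_matrix
from .spectra_io import N_BANDS, WAVELENGTHS, WL_MIN, Dataset, water_band_mask
from .wavelet_bank import registry_by_name

__all__ = [
    "Scalogram",
    "FeatureSpec",
    "OccurrenceMap",
    "FunctionRanking",
    "r2_matrix",
    "scalogram_r2",
    "scalogram_from_coefficients",
    "top_fraction",
    "occurrence_map",
    "rank_functions",
    "contiguous_regions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class FeatureSpec:
    """One wavelet feature: (function, wavelength W in nm, scale exponent S)."""

    function: str
    wavelength: int
    scale_exponent: int


@dataclass
class Scalogram:
    """Calibration R^2 over the (scale, wavelength) plane for one function.

    ``r2`` carries NaN sentinels at ineligible cells so they can never win
    a ranking; ``r2_all`` keeps the computed value everywhere for export
    and plotting.
    """

    function: str
    scale_exponents: tuple[int, ...]
    r2_all: np.ndarray
    eligible: np.ndarray

    @property
    def r2(self) -> np.ndarray:
        out = np.where(self.eligible, self.r2_all, np.nan)
        return out

    def best(self) -> tuple[float, FeatureSpec]:
        """Highest eligible R^2 and its feature (ties: higher S, lower W)."""
        feats = top_fraction(self, q=1.0 / max(self.eligible.sum(), 1))
        f = feats[0]
        si = self.scale_exponents.index(f.scale_exponent)
        return float(self.r2_all[si, f.wavelength - WL_MIN]), f

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.scale_exponents):
            rows.append(
                pd.DataFrame(
                    {
                        "function": self.function,
                        "scale_exponent": s,
                        "wavelength": WAVELENGTHS,
                        "r2": self.r2_all[si],
                        "eligible": self.eligible[si],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class OccurrenceMap:
    """Per-cell count of functions whose top-q set contains the cell."""

    scale_exponents: tuple[int, ...]
    counts: np.ndarray  # (n_scales, 2151) int

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.scale_exponents):
            nz = np.nonzero(self.counts[si])[0]
            rows.append(
                pd.DataFrame(
                    {
                        "scale_exponent": s,
                        "wavelength": WAVELENGTHS[nz],
                        "count": self.counts[si, nz],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["scale_exponent", "wavelength", "count"]
        )


@dataclass
class FunctionRanking:
    """Box-plot ranking of mother wavelets by best calibration R^2."""

    best: dict[str, float]
    ranking: list[tuple[str, float]]
    optimal: set[str]
    poor: set[str]
    q1: float
    q3: float
    family_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def r2_matrix(coefficients: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of the trait with every coefficient cell.

    ``coefficients`` has shape (n_samples, n_scales, n_bands).  Cells with
    zero coefficient variance get R^2 = 0 (logged), matching the OLS R^2
    of the simple linear model elsewhere.
    """
    X = np.asarray(coefficients, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples to correlate, got {n}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ijk,ijk->jk", Xc, Xc)
    sxy = np.einsum("ijk,i->jk", Xc, yc)
    syy = float(yc @ yc)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (sxy * sxy) / np.where(denom > 0, denom, 1.0), 0.0)
    n_degenerate = int((sxx <= 0).sum())
    if n_degenerate:
        logger.info("%d zero-variance cells set to r2 = 0", n_degenerate)
    return np.clip(r2, 0.0, 1.0)


def scalogram_from_coefficients(coefficients: np.ndarray, y: np.ndarray,
                                function: str, boundary: np.ndarray,
                                scale_exponents=DEFAULT_SCALE_EXPONENTS) -> Scalogram:
    r2 = r2_matrix(coefficients, y)
    eligible = ~boundary & ~water_band_mask()[None, :]
    return Scalogram(
        function=function,
        scale_exponents=tuple(int(s) for s in scale_exponents),
        r2_all=r2,
        eligible=eligible,
    )


def scalogram_r2(dataset: Dataset, function, scale_exponents=DEFAULT_SCALE_EXPONENTS,
                 resolution_exponent: int = 10) -> Scalogram:
    """Correlation scalogram of one function over the calibration samples."""
    _, refl, clb, _ = dataset.to_arrays("calibration")
    if refl.shape[0] < 3:
        raise ValueError(
            f"need at least 3 calibration samples, got {refl.shape[0]}"
        )
    name = function if isinstance(function, str) else function.name
    coefs, boundary, _ = cwt_matrix(refl, name, scale_exponents, resolution_exponent)
    return scalogram_from_coefficients(coefs, clb, name, boundary, scale_exponents)


def top_fraction(scalogram: Scalogram, q: float = 0.01) -> list[FeatureSpec]:
    """The ceil(q * E) best eligible cells, E = number of eligible cells.

    Ties at the cutoff break deterministically towards higher scale, then
    lower wavelength.  Returned in rank order.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    elig = scalogram.eligible
    E = int(elig.sum())
    if E == 0:
        return []
    k = ceil(q * E)
    si, wi = np.nonzero(elig)
    r2 = scalogram.r2_all[si, wi]
    scales = np.array([scalogram.scale_exponents[i] for i in si])
    order = np.lexsort((WAVELENGTHS[wi], -scales, -r2))
    chosen = order[:k]
    return [
        FeatureSpec(scalogram.function, int(WAVELENGTHS[wi[i]]), int(scales[i]))
        for i in chosen
    ]


def occurrence_map(top_sets: dict[str, list[FeatureSpec]],
                   scale_exponents=DEFAULT_SCALE_EXPONENTS) -> OccurrenceMap:
    """Count, per (W, S) cell, how many functions selected it."""
    scale_exponents = tuple(int(s) for s in scale_exponents)
    counts = np.zeros((len(scale_exponents), N_BANDS), int)
    for feats in top_sets.values():
        for f in set(feats):
            counts[scale_exponents.index(f.scale_exponent), f.wavelength - WL_MIN] += 1
    return OccurrenceMap(scale_exponents=scale_exponents, counts=counts)


def rank_functions(best_r2: dict[str, float]) -> FunctionRanking:
    """Box-plot (1.5 IQR, linear-interpolation quartiles) function ranking.

    ``optimal`` are upper outliers (best R^2 above Q3 + 1.5 IQR), ``poor``
    lower outliers; the full ranking is sorted descending (ties by name).
    """
    if len(best_r2) < 4:
        raise ValueError(f"need at least 4 functions to rank, got {len(best_r2)}")
    values = np.array(list(best_r2.values()), float)
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    hi, lo = q3 + 1.5 * iqr, q1 - 1.5 * iqr
    optimal = {n for n, v in best_r2.items() if v > hi}
    poor = {n for n, v in best_r2.items() if v < lo}
    ranking = sorted(best_r2.items(), key=lambda kv: (-kv[1], kv[0]))
    by_name = registry_by_name()
    fam = pd.DataFrame(
        {
            "family": [by_name[n].family if n in by_name else "?" for n in best_r2],
            "best_r2": list(best_r2.values()),
        }
    )
    summary = (
        fam.groupby("family")["best_r2"]
        .agg(["count", "min", "median", "max"])
        .reset_index()
        .sort_values("max", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return FunctionRanking(
        best=dict(best_r2),
        ranking=ranking,
        optimal=optimal,
        poor=poor,
        q1=float(q1),
        q3=float(q3),
        family_summary=summary,
    )


def contiguous_regions(top_set: list[FeatureSpec]) -> list[tuple[int, tuple[int, int]]]:
    """Maximal runs of grid-adjacent wavelengths within one scale.

    Returns closed intervals as (scale_exponent, (start_nm, end_nm)),
    sorted by (scale, start).
    """
    by_scale: dict[int, list[int]] = {}
    for f in top_set:
        by_scale.setdefault(f.scale_exponent, []).append(f.wavelength)
    regions = []
    for s in sorted(by_scale):
        wls = sorted(set(by_scale[s]))
        start = prev = wls[0]
        for w in wls[1:]:
            if w == prev + 1:
                prev = w
                continue
            regions.append((s, (start, prev)))
            start = prev = w
        regions.append((s, (start, prev)))
    return regions
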