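"""Single-feature trait models and their evaluation.

A selected wavelet feature (function, W, S) -- or a two-band vegetation
index -- supplies a scalar regressor x per sample, and the trait is
modelled as y = slope * x + intercept by ordinary least squares on the
calibration set.  Validation reports the squared Pearson correlation of
predictions with observations (the 1:1-plot convention; the
1 - SSE/SST variant is exported alongside) and the relative root mean
square error

    RRMSE = 100 * sqrt(mean((P_i - O_i)^2)) / mean(O),

in percent of the mean observed trait.  Subgroup reports re-evaluate the
single global model inside sample subgroups (growth stage, site, variety,
year) without refitting, appending unweighted subgroup means.

The influence profile of a feature is the exact sensitivity of its
coefficient to each 1-nm reflectance band, i.e. the discrete quadrature
kernel of the transform centred on W with width set by 2**S; its local
extrema identify the wavelengths that drive the feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from .cwt_engine import scaled_kernel
from .screening import FeatureSpec
from .spectra_io import N_BANDS, WAVELENGTHS, WL_MIN, WL_MAX, SpectralSample

__all__ = [
    "LinearModel",
    "ValidationReport",
    "VIDefinition",
    "NDVI_BLEAF",
    "RVI_GBM",
    "fit_linear",
    "rrmse",
    "validate",
    "vi_value",
    "subgroup_report",
    "influence_profile",
    "InfluenceProfile",
    "classify_feature_position",
]

logger = logging.getLogger(__name__)


@dataclass
class LinearModel:
    """Calibrated simple linear model y = slope * x + intercept."""

    feature: FeatureSpec | str
    slope: float
    intercept: float
    rc2: float
    se: float  # standard error of estimate, trait units
    n_cal: int

    @property
    def equation(self) -> str:
        return f"Y = {self.slope:.3f}x{self.intercept:+.3f}"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass
class ValidationReport:
    rv2: float
    rv2_sse: float  # 1 - SSE/SST variant
    rrmse: float  # percent
    n_val: int
    predictions: np.ndarray
    observations: np.ndarray
    grouping: str | None = None
    subgroups: pd.DataFrame | None = None


@dataclass(frozen=True)
class VIDefinition:
    """Two-band vegetation index: normalized-difference or simple-ratio."""

    name: str
    band_a: int
    band_b: int
    form: str  # "normalized-difference" | "simple-ratio"

    def __post_init__(self):
        for b in (self.band_a, self.band_b):
            if not (WL_MIN <= b <= WL_MAX):
                raise ValueError(f"{self.name}: band {b} nm off the grid")
        if self.form not in ("normalized-difference", "simple-ratio"):
            raise ValueError(f"{self.name}: unknown form {self.form!r}")


#: canopy foliar biomass NDVI baseline, bands 2160 / 1540 nm
NDVI_BLEAF = VIDefinition("NDVI_Bleaf", 2160, 1540, "normalized-difference")
#: green biomass simple-ratio baseline, bands 708 / 565 nm
RVI_GBM = VIDefinition("RVI_GBM", 708, 565, "simple-ratio")


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        logger.info("degenerate (zero-variance) correlation defined as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def fit_linear(x: np.ndarray, y: np.ndarray,
               feature: FeatureSpec | str = "feature") -> LinearModel:
    """Ordinary least squares y = slope * x + intercept.

    ``rc2`` is the squared Pearson correlation; ``se`` the standard error
    of estimate sqrt(SSE / (n - 2)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 to fit, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if x.std() == 0:
        raise ValueError("zero-variance regressor")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    se = float(np.sqrt((resid @ resid) / (n - 2)))
    return LinearModel(
        feature=feature,
        slope=float(res.slope),
        intercept=float(res.intercept),
        rc2=float(res.rvalue**2),
        se=se,
        n_cal=n,
    )


def rrmse(predictions: np.ndarray, observations: np.ndarray) -> float:
    """Relative RMSE in percent of the mean observation."""
    P = np.asarray(predictions, float)
    O = np.asarray(observations, float)
    if P.shape != O.shape or P.size == 0:
        raise ValueError("predictions and observations must be equal-length, non-empty")
    obar = O.mean()
    if obar == 0:
        raise ValueError("mean observation is zero; RRMSE undefined")
    return float(100.0 * np.sqrt(np.mean((P - O) ** 2)) / obar)


def validate(model: LinearModel, x: np.ndarray, y: np.ndarray) -> ValidationReport:
    """Evaluate a calibrated model on a validation set (no refitting)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0:
        raise ValueError("empty validation set")
    P = model.predict(x)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - P) ** 2))
    rv2_sse = 1.0 - sse / sst if sst > 0 else 0.0
    return ValidationReport(
        rv2=_pearson_r2(P, y),
        rv2_sse=rv2_sse,
        rrmse=rrmse(P, y),
        n_val=len(y),
        predictions=P,
        observations=y,
    )


def vi_value(sample, vi: VIDefinition):
    """Vegetation-index value(s) for a sample or reflectance matrix."""
    if isinstance(sample, SpectralSample):
        refl = sample.reflectance[None, :]
        scalar = True
    else:
        refl = np.atleast_2d(np.asarray(sample, float))
        scalar = refl.shape[0] == 1 and np.asarray(sample).ndim == 1
    ra = refl[:, vi.band_a - WL_MIN]
    rb = refl[:, vi.band_b - WL_MIN]
    if vi.form == "normalized-difference":
        denom = ra + rb
        if np.any(denom == 0):
            raise ZeroDivisionError(f"{vi.name}: zero band sum")
        out = (ra - rb) / denom
    else:
        if np.any(rb == 0):
            raise ZeroDivisionError(f"{vi.name}: zero denominator band")
        out = ra / rb
    return float(out[0]) if scalar else out


def subgroup_report(model: LinearModel, x: np.ndarray, y: np.ndarray,
                    groups: pd.Series | np.ndarray, grouping: str,
                    min_n: int = 3) -> ValidationReport:
    """Per-subgroup validation of one global model, with mean rows.

    Subgroups with fewer than ``min_n`` samples are listed with metrics
    suppressed (NaN) and flagged.  The appended mean row is the unweighted
    arithmetic mean of the reported subgroup metrics.
    """
    overall = validate(model, x, y)
    groups = pd.Series(np.asarray(groups), name=grouping)
    rows = []
    for g in sorted(groups.unique(), key=str):
        sel = (groups == g).to_numpy()
        n = int(sel.sum())
        if n < min_n:
            rows.append(
                {"grouping": grouping, "subgroup": str(g), "n": n,
                 "rv2": np.nan, "rrmse": np.nan, "flagged": True}
            )
            continue
        rep = validate(model, x[sel], y[sel])
        rows.append(
            {"grouping": grouping, "subgroup": str(g), "n": n,
             "rv2": rep.rv2, "rrmse": rep.rrmse, "flagged": False}
        )
    df = pd.DataFrame(rows)
    ok = df[~df["flagged"]]
    df = pd.concat(
        [
            df,
            pd.DataFrame(
                [{
                    "grouping": grouping, "subgroup": "Mean",
                    "n": int(df["n"].sum()),
                    "rv2": ok["rv2"].mean() if len(ok) else np.nan,
                    "rrmse": ok["rrmse"].mean() if len(ok) else np.nan,
                    "flagged": False,
                }]
            ),
        ],
        ignore_index=True,
    )
    overall.grouping = grouping
    overall.subgroups = df
    return overall


@dataclass
class InfluenceProfile:
    """Per-wavelength sensitivity of one wavelet feature."""

    feature: FeatureSpec
    sensitivity: np.ndarray  # (2151,), |kernel weight| for complex psi
    influential: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength": WAVELENGTHS, "sensitivity": self.sensitivity}
        )


def influence_profile(wavelet, wavelength: int, scale_exponent: int,
                      resolution_exponent: int = 10,
                      rel_threshold: float = 0.05) -> InfluenceProfile:
    """Sensitivity of C(W, S) to each reflectance band.

    The coefficient is linear in the spectrum, so the sensitivity is the
    quadrature kernel weight of each 1-nm band: the scaled, conjugated
    wavelet centred at W with width set by 2**S (its modulus for complex
    psi).  Local extrema of |sensitivity| above ``rel_threshold`` of the
    maximum are reported as influential wavelengths, strongest first.
    """
    if not (WL_MIN <= wavelength <= WL_MAX):
        raise ValueError(f"wavelength {wavelength} off grid")
    g, m_min = scaled_kernel(wavelet, scale_exponent, resolution_exponent)
    sens = np.zeros(N_BANDS, dtype=g.dtype)
    idx = wavelength - WL_MIN
    m = np.arange(m_min, m_min + len(g))
    j = idx + m
    ok = (j >= 0) & (j < N_BANDS)
    sens[j[ok]] = g[ok]
    if np.iscomplexobj(sens):
        sens = np.abs(sens)
    mag = np.abs(sens)
    (peaks,) = argrelextrema(mag, np.greater_equal, order=2)
    peaks = peaks[mag[peaks] >= rel_threshold * mag.max()]
    # deduplicate flat runs
    keep = [p for i, p in enumerate(peaks) if i == 0 or p > peaks[i - 1] + 2]
    keep.sort(key=lambda p: -mag[p])
    name = wavelet if isinstance(wavelet, str) else getattr(wavelet, "name", str(wavelet))
    return InfluenceProfile(
        feature=FeatureSpec(name, wavelength, scale_exponent),
        sensitivity=np.asarray(sens, float),
        influential=[int(WAVELENGTHS[p]) for p in keep],
    )


def classify_feature_position(mean_profile: np.ndarray, wavelength: int,
                              window: int = 2) -> str:
    """Classify W on the mean coefficient profile at its scale.

    ``zero-crossing`` if the profile changes sign within +-``window`` nm,
    else ``peak`` / ``valley`` for a local maximum / minimum of the
    profile; precedence zero-crossing > peak > valley.  Monotone
    non-crossing neighbourhoods fall back on the local curvature.
    """
    profile = np.asarray(mean_profile, float)
    if profile.shape != (N_BANDS,):
        raise ValueError(f"profile must cover the {N_BANDS}-band grid")
    if not np.all(np.isfinite(profile)):
        raise ValueError("non-finite profile")
    idx = wavelength - WL_MIN
    if idx - window < 0 or idx + window >= N_BANDS:
        raise ValueError(f"wavelength {wavelength} too close to the grid boundary")
    seg = profile[idx - window: idx + window + 1]
    signs = np.sign(seg)
    nz = signs[signs != 0]
    if len(nz) == 0 or np.any(nz[1:] != nz[:-1]) or np.any(signs == 0):
        return "zero-crossing"
    v = profile[idx]
    if v >= seg.max():
        return "peak"
    if v <= seg.min():
        return "valley"
    curvature = profile[idx - 1] - 2 * v + profile[idx + 1]
    return "peak" if curvature < 0 else "valley"
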