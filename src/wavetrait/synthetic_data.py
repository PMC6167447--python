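"""Synthetic canopy reflectance datasets with a planted wavelet feature.

The generator is phenomenological: each spectrum is a mixture of a bright
soil line and a green-leaf signature (green bump near 550 nm, chlorophyll
trough near 680 nm, red edge at 700-750 nm, NIR plateau to 1350 nm, water
dips near 1450/1940 nm), with the canopy fraction following a saturating
Beer-Lambert response 1 - exp(-k * CLB) to the latent canopy leaf biomass
(CLB, kg/m^2).  Correlated smooth noise (about 30 nm correlation length)
and white sensor noise emulate field variability, and the three water
windows are zeroed exactly as real spectra are preprocessed.

On top of that diffuse response, one chosen cell of the coefficient plane
-- (planted function, W*, S*) -- is given an exactly known relationship to
CLB: a structured perturbation shaped like the planted wavelet is added to
each spectrum so that, after the transform, the planted-cell coefficient
equals an affine function of CLB plus a controlled noise term whose
amplitude is tuned by bisection until the sample squared correlation with
CLB matches ``target_cell_r2``.  Because the transform is linear, this
construction is exact: at ``target_cell_r2 = 1`` the planted cell
correlates perfectly regardless of the other noise sources.  The planted
relationship is therefore the known-best cell that screening should
recover, while the saturating canopy response supplies realistic,
weaker, diffuse correlations everywhere else.

Samples are organised into pseudo-experiments with per-experiment biomass
level shifts (sizes default to a 1502-sample, eight-experiment layout)
and split calibration/validation at the experiment level, approximately
2:1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .cwt_engine import cwt_matrix
from .spectra_io import (
    N_BANDS,
    WAVELENGTHS,
    WL_MIN,
    Dataset,
    SpectralSample,
    TraitRecord,
    assign_split,
    water_band_mask,
)
from .wavelet_bank import evaluate_psi, registry_by_name

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "DEFAULT_EXPERIMENT_SIZES",
    "generate",
    "truth_record",
    "write_truth",
    "read_truth",
    "planted_cell_r2",
]

#: per-experiment sample counts of the default eight-experiment layout
DEFAULT_EXPERIMENT_SIZES = (127, 219, 136, 126, 285, 203, 240, 166)

_EXPERIMENT_META = {
    "exp1": ("JAAS", 2004, ("Ningmai 9", "Huaimai 20", "Yangmai 10", "Xumai 26")),
    "exp2": ("JAAS", 2005, ("Ningmai 9", "Yumai 34", "Yangmai 10")),
    "exp3": ("NAFB", 2006, ("Ningmai 9", "Yumai 34")),
    "exp4": ("NJAU", 2008, ("Ningmai 9",)),
    "exp5": ("YCY", 2010, ("Yangmai 16", "Aikang 58")),
    "exp6": ("YCY", 2010, ("Yangmai 16",)),
    "exp7": ("YCY", 2010, ("Ningmai 13", "Yangmai 16")),
    "exp8": ("YCY", 2011, ("Yangmai 16",)),
}

_SAMPLING_DATES = ("03-10", "03-25", "04-05", "04-18", "04-30", "05-12")
_ANTHESIS_CUTOFF = "04-15"


class SimulationError(RuntimeError):
    """Unattainable simulation target or implausible configuration."""


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic dataset.

    ``target_cell_r2`` is the squared correlation between CLB and the
    planted-cell coefficient, achieved to +-0.02 (in practice much
    tighter) by bisection on the structured-noise amplitude.
    """

    n_samples: int = 1502
    seed: int = 0
    clb_range: tuple[float, float] = (0.0096, 0.330)
    planted_function: str = "db7"
    planted_wavelength: int = 1100
    planted_scale: int = 5
    target_cell_r2: float = 0.8
    experiment_sizes: tuple[int, ...] | None = None
    calibration_experiments: tuple[str, ...] = ("exp2", "exp4", "exp5", "exp7", "exp8")
    #: Beer-Lambert canopy extinction against CLB, m^2/kg
    canopy_extinction: float = 12.0
    #: lognormal-ish scatter of canopy cover around its CLB response
    cover_jitter_sd: float = 0.08
    noise_smooth_sd: float = 0.01
    noise_smooth_length: float = 30.0
    noise_white_sd: float = 0.002
    resolution_exponent: int = 10

    def __post_init__(self):
        if not (0 < self.target_cell_r2 <= 1):
            raise ValueError("target_cell_r2 must be in (0, 1]")
        if self.clb_range[0] <= 0 or self.clb_range[1] <= self.clb_range[0]:
            raise ValueError("clb_range must be positive and increasing")
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        spec = registry_by_name().get(self.planted_function)
        if spec is None:
            raise ValueError(f"unknown planted function {self.planted_function!r}")
        if spec.is_complex:
            raise ValueError(
                "planted function must be real-valued: the modulus realization "
                "of complex coefficients breaks the exact planted construction"
            )


def _experiment_sizes(config: SimulationConfig) -> list[int]:
    base = config.experiment_sizes or DEFAULT_EXPERIMENT_SIZES
    total = sum(base)
    if config.experiment_sizes is not None or total == config.n_samples:
        if sum(base) != config.n_samples and config.experiment_sizes is not None:
            raise ValueError("experiment_sizes must sum to n_samples")
        return list(base)
    # largest-remainder proportional scaling of the default layout
    quota = [config.n_samples * b / total for b in base]
    sizes = [int(q) for q in quota]
    rem = config.n_samples - sum(sizes)
    order = np.argsort([int(q) - q for q in quota])
    for i in order[:rem]:
        sizes[i] += 1
    if min(sizes) == 0:
        raise ValueError("n_samples too small for eight pseudo-experiments")
    return sizes


def _leaf_signature(lam: np.ndarray) -> np.ndarray:
    G = lambda c, s: np.exp(-0.5 * ((lam - c) / s) ** 2)  # noqa: E731
    S = lambda c, s: 1.0 / (1.0 + np.exp(-(lam - c) / s))  # noqa: E731
    vis = 0.05 + 0.055 * G(550, 22) - 0.015 * G(670, 30)
    envelope = 1.0 - 0.62 * S(1480, 170)
    dips = (
        1.0
        - 0.04 * G(970, 40)
        - 0.10 * G(1200, 55)
        - 0.55 * G(1450, 55)
        - 0.75 * G(1940, 90)
        - 0.30 * G(2500, 250)
    )
    return vis + 0.50 * S(715, 16) * envelope * np.clip(dips, 0.05, 1.0)


def _soil_signature(lam: np.ndarray) -> np.ndarray:
    return 0.12 + 0.20 * (lam - WL_MIN) / (lam[-1] - WL_MIN)


def _planted_pattern(config: SimulationConfig) -> np.ndarray:
    """Unit-amplitude copy of the planted wavelet, scaled and centred on W*."""
    sw = evaluate_psi(config.planted_function, config.resolution_exponent)
    a = 2 ** config.planted_scale
    u = sw.grid - 0.5 * (sw.grid[0] + sw.grid[-1])
    p = np.interp(
        (WAVELENGTHS - config.planted_wavelength) / a, u, sw.psi, left=0.0, right=0.0
    )
    peak = np.abs(p).max()
    if peak == 0:
        raise SimulationError("planted pattern is identically zero")
    return p / peak


def generate(config: SimulationConfig) -> Dataset:
    """Simulate a masked, split dataset with the planted feature.

    Deterministic in ``config.seed``.  Raises :class:`SimulationError`
    when the planted cell is ineligible (masked, boundary-dependent) or
    the target cell R^2 cannot be reached under the configured noise.
    """
    rng = np.random.default_rng(config.seed)
    lam = WAVELENGTHS.astype(float)
    sizes = _experiment_sizes(config)
    exp_ids = [f"exp{i + 1}" for i in range(len(sizes))]
    n = config.n_samples

    # latent biomass with per-experiment level shifts
    lo, hi = config.clb_range
    exp_factor = rng.uniform(0.75, 1.25, size=len(sizes))
    clb = np.empty(n)
    experiment = np.empty(n, dtype=object)
    pos = 0
    for eid, size, fac in zip(exp_ids, sizes, exp_factor):
        draw = lo + (hi - lo) * rng.beta(2.0, 3.0, size=size)
        clb[pos: pos + size] = np.clip(draw * fac, lo, hi)
        experiment[pos: pos + size] = eid
        pos += size

    # canopy mixture with saturating cover response
    cover = 1.0 - np.exp(-config.canopy_extinction * clb)
    cover = cover * (1.0 + config.cover_jitter_sd * rng.standard_normal(n))
    cover = np.clip(cover, 0.02, 0.99)
    soil = _soil_signature(lam) * (1.0 + 0.10 * rng.standard_normal(n))[:, None]
    leaf = _leaf_signature(lam)
    refl = (1.0 - cover[:, None]) * soil + cover[:, None] * leaf[None, :]

    # correlated smooth noise + white sensor noise
    if config.noise_smooth_sd > 0:
        smooth = gaussian_filter1d(
            rng.standard_normal((n, N_BANDS)), config.noise_smooth_length, axis=1
        )
        sd = smooth.std(axis=1, keepdims=True)
        refl = refl + config.noise_smooth_sd * smooth / np.where(sd > 0, sd, 1.0)
    if config.noise_white_sd > 0:
        refl = refl + config.noise_white_sd * rng.standard_normal((n, N_BANDS))

    mask = water_band_mask()
    refl[:, mask] = 0.0

    # ---- planted relationship -------------------------------------------
    p = _planted_pattern(config)
    if np.any(np.abs(p[mask]) > 1e-12):
        raise SimulationError(
            "planted cell ineligible: wavelet support overlaps a water window"
        )
    bidx = config.planted_wavelength - WL_MIN
    coefs, boundary, _ = cwt_matrix(
        refl, config.planted_function, [config.planted_scale],
        config.resolution_exponent,
    )
    if boundary[0, bidx]:
        raise SimulationError("planted cell ineligible: boundary-dependent shift")
    c = coefs[:, 0, bidx]
    kappa = cwt_matrix(
        p[None, :], config.planted_function, [config.planted_scale],
        config.resolution_exponent,
    )[0][0, 0, bidx]
    if abs(kappa) < 1e-12:
        raise SimulationError("planted pattern has zero response at the planted cell")

    z = clb - clb.mean()
    z_norm = z / z.std()
    sd_c = c.std()
    if sd_c == 0:
        sd_c = 1e-3
    y = c.mean() + sd_c * z_norm

    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - (e @ z_norm) / (z_norm @ z_norm) * z_norm
    if e.std() == 0:
        raise SimulationError("degenerate structured-noise direction")
    e = e / e.std()

    def achieved(sigma: float) -> float:
        x = y + sigma * sd_c * e
        return float(np.corrcoef(clb, x)[0, 1] ** 2)

    target = config.target_cell_r2
    sigma = 0.0
    if target < 1.0:
        hi_s = 1.0
        for _ in range(60):
            if achieved(hi_s) < target:
                break
            hi_s *= 2.0
        else:
            raise SimulationError(
                f"cannot bracket target_cell_r2={target}: achieved "
                f"{achieved(hi_s):.4f} at noise amplitude {hi_s:g}"
            )
        lo_s = 0.0
        for _ in range(80):
            mid = 0.5 * (lo_s + hi_s)
            if achieved(mid) >= target:
                lo_s = mid
            else:
                hi_s = mid
        sigma = 0.5 * (lo_s + hi_s)
    if abs(achieved(sigma) - target) > 0.02:
        raise SimulationError(
            f"bisection failed: achieved {achieved(sigma):.4f}, target {target}"
        )

    x_target = y + sigma * sd_c * e
    delta = (x_target - c) / kappa
    refl = refl + delta[:, None] * p[None, :]
    refl[:, mask] = 0.0

    if refl.min() < 0.0 or refl.max() > 1.0:
        raise SimulationError(
            f"simulated reflectance out of [0, 1] "
            f"(min {refl.min():.3f}, max {refl.max():.3f}); "
            "reduce noise or planted amplitudes"
        )

    # ---- assemble dataset ------------------------------------------------
    samples, traits = [], []
    for i in range(n):
        sid = f"s{i:05d}"
        eid = experiment[i]
        site, year, varieties = _EXPERIMENT_META.get(
            eid, ("site?", 2004, ("Ningmai 9",))
        )
        date = f"{year}-{_SAMPLING_DATES[rng.integers(len(_SAMPLING_DATES))]}"
        stage = "before" if date[5:] <= _ANTHESIS_CUTOFF else "after"
        variety = varieties[rng.integers(len(varieties))]
        samples.append(
            SpectralSample(sample_id=sid, reflectance=refl[i], mask=mask.copy())
        )
        traits.append(
            TraitRecord(
                sample_id=sid,
                clb=float(clb[i]),
                experiment_id=eid,
                site=site,
                variety=variety,
                sampling_date=date,
                growth_stage=stage,
            )
        )
    dataset = Dataset(samples=samples, traits=traits)
    cal = tuple(e for e in config.calibration_experiments if e in set(exp_ids))
    return assign_split(dataset, cal)


def truth_record(config: SimulationConfig) -> dict:
    """Machine-readable planted ground truth for recovery harnesses."""
    return {
        "planted_function": config.planted_function,
        "planted_wavelength": config.planted_wavelength,
        "planted_scale": config.planted_scale,
        "target_cell_r2": config.target_cell_r2,
        "seed": config.seed,
    }


def write_truth(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth_record(config), indent=2) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def planted_cell_r2(dataset: Dataset, config: SimulationConfig) -> float:
    """Recompute the achieved squared correlation at the planted cell."""
    _, refl, clb, _ = dataset.to_arrays()
    coefs, _, _ = cwt_matrix(
        refl, config.planted_function, [config.planted_scale],
        config.resolution_exponent,
    )
    x = coefs[:, 0, config.planted_wavelength - WL_MIN]
    return float(np.corrcoef(clb, x)[0, 1] ** 2)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["clb_range"] = list(config.clb_range)
    return d
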