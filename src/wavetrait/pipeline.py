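"""End-to-end screening runs: configuration, orchestration, artifacts.

``run_screen`` executes the whole procedure -- transform every candidate
mother wavelet, build its correlation scalogram on the calibration split,
pool the top-q feature sets into an occurrence map, rank the functions by
the box-plot rule, calibrate and validate single-feature models for the
best features of the winning function, compare against the two-band
vegetation-index baselines on the identical split, and characterise the
winning feature (influence profile, peak/valley/zero-crossing class).
All artifacts are delimited text tables plus a YAML manifest (config,
seed, config hash, package version -- no timestamps), so a rerun from one
manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cwt_engine import DEFAULT_SCALE_EXPONENTS, cwt_matrix
from .modeling import (
    NDVI_BLEAF,
    RVI_GBM,
    LinearModel,
    classify_feature_position,
    fit_linear,
    influence_profile,
    subgroup_report,
    validate,
    vi_value,
)
from .screening import (
    FeatureSpec,
    Scalogram,
    contiguous_regions,
    occurrence_map,
    rank_functions,
    scalogram_from_coefficients,
    top_fraction,
)
from .spectra_io import (
    WL_MIN,
    Dataset,
    apply_water_band_mask,
    assign_split,
    read_spectra_table,
    read_trait_table,
)
from .synthetic_data import SimulationConfig, generate
from .wavelet_bank import registry_by_name

__all__ = ["RunConfig", "RunResult", "run_screen", "load_dataset"]

logger = logging.getLogger(__name__)

_GROUPINGS = (
    ("anthesis", "growth_stage"),
    ("site", "site"),
    ("variety", "variety"),
    ("year", "year"),
)


@dataclass
class RunConfig:
    """Configuration of one screening run.

    Either ``simulation`` (synthetic data) or ``spectra_path`` +
    ``traits_path`` + ``calibration_experiments`` (tabular data) must be
    given.  ``functions`` of None means the full 108-function registry.
    """

    simulation: SimulationConfig | None = None
    spectra_path: str | None = None
    traits_path: str | None = None
    calibration_experiments: tuple[str, ...] | None = None
    functions: tuple[str, ...] | None = None
    scale_exponents: tuple[int, ...] = DEFAULT_SCALE_EXPONENTS
    top_q: float = 0.01
    n_best_features: int = 5
    vi_baselines: bool = True
    output_dir: str | None = None
    seed: int = 0
    resolution_exponent: int = 10
    max_failure_fraction: float = 0.10

    def __post_init__(self):
        if not (0 < self.top_q < 1):
            raise ValueError(f"top_q must be in (0, 1), got {self.top_q}")
        if self.functions is not None:
            known = registry_by_name()
            bad = [f for f in self.functions if f not in known]
            if bad:
                raise ValueError(f"unknown function name(s): {bad}")
        if self.simulation is None and not (self.spectra_path and self.traits_path):
            raise ValueError("either simulation or spectra/traits paths required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=SimulationConfig(**_tupled(sim)) if sim else None,
            **_tupled(raw),
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return _listed(d)


def _tupled(d: dict | None) -> dict:
    d = dict(d or {})
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return d


def _listed(obj):
    if isinstance(obj, dict):
        return {k: _listed(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listed(v) for v in obj]
    return obj


@dataclass
class RunResult:
    config: RunConfig
    dataset: Dataset
    scalograms: dict[str, Scalogram]
    top_sets: dict[str, list[FeatureSpec]]
    ranking: object
    occurrence: object
    winner: str
    models: list[tuple[LinearModel, object]]  # (model, validation report)
    comparison: pd.DataFrame
    subgroups: pd.DataFrame
    influence: object
    position_class: str
    regions: list
    failures: dict[str, str] = field(default_factory=dict)


def load_dataset(config: RunConfig) -> Dataset:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        return generate(sim)
    samples = [apply_water_band_mask(s) for s in read_spectra_table(config.spectra_path)]
    traits = read_trait_table(config.traits_path)
    ds = Dataset(samples=samples, traits=traits)
    if not config.calibration_experiments:
        raise ValueError("calibration_experiments required for tabular input")
    return assign_split(ds, config.calibration_experiments)


def _feature_values(refl: np.ndarray, feat: FeatureSpec, config: RunConfig) -> np.ndarray:
    coefs, _, _ = cwt_matrix(
        refl, feat.function, [feat.scale_exponent], config.resolution_exponent
    )
    return coefs[:, 0, feat.wavelength - WL_MIN]


def run_screen(config: RunConfig) -> RunResult:
    """Execute the full screening procedure; optionally write artifacts."""
    dataset = load_dataset(config)
    _, cal_refl, cal_clb, _ = dataset.to_arrays("calibration")
    _, val_refl, val_clb, val_meta = dataset.to_arrays("validation")
    if cal_refl.shape[0] < 3:
        raise ValueError("need at least 3 calibration samples")
    if val_refl.shape[0] == 0:
        raise ValueError("empty validation split")

    names = list(config.functions or [s.name for s in registry_by_name().values()])
    scalograms: dict[str, Scalogram] = {}
    top_sets: dict[str, list[FeatureSpec]] = {}
    best: dict[str, float] = {}
    failures: dict[str, str] = {}
    for name in names:
        t0 = time.perf_counter()
        try:
            coefs, boundary, _ = cwt_matrix(
                cal_refl, name, config.scale_exponents, config.resolution_exponent
            )
            sg = scalogram_from_coefficients(
                coefs, cal_clb, name, boundary, config.scale_exponents
            )
            scalograms[name] = sg
            top_sets[name] = top_fraction(sg, config.top_q)
            best[name], _ = sg.best()
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            failures[name] = str(exc)
            logger.error("function %s failed: %s", name, exc)
        logger.info("screened %s in %.2fs", name, time.perf_counter() - t0)
    if len(failures) > config.max_failure_fraction * len(names):
        raise RuntimeError(
            f"{len(failures)}/{len(names)} functions failed: {failures}"
        )

    occ = occurrence_map(top_sets, config.scale_exponents)
    ranking = rank_functions(best)
    winner = ranking.ranking[0][0]

    # best features of the winning function, models + validation
    win_sg = scalograms[winner]
    k = max(config.n_best_features, 1)
    win_feats = top_fraction(win_sg, q=min(k / max(win_sg.eligible.sum(), 1), 0.999))[:k]
    models = []
    for feat in win_feats:
        x_cal = _feature_values(cal_refl, feat, config)
        x_val = _feature_values(val_refl, feat, config)
        model = fit_linear(x_cal, cal_clb, feature=feat)
        report = validate(model, x_val, val_clb)
        models.append((model, report))

    # subgroup stability of the top model
    top_feat = win_feats[0]
    x_val_top = _feature_values(val_refl, top_feat, config)
    sub_frames = []
    for label, col in _GROUPINGS:
        rep = subgroup_report(models[0][0], x_val_top, val_clb, val_meta[col], label)
        sub_frames.append(rep.subgroups)
    subgroups = pd.concat(sub_frames, ignore_index=True)

    # comparison table on the identical split
    rows = []
    m0, r0 = models[0]
    rows.append(
        {
            "feature": f"{winner} (W{top_feat.wavelength}, S{top_feat.scale_exponent})",
            "kind": "wavelet",
            "equation": m0.equation,
            "rc2": m0.rc2,
            "se": m0.se,
            "rv2": r0.rv2,
            "rrmse": r0.rrmse,
        }
    )
    if config.vi_baselines:
        for vi in (NDVI_BLEAF, RVI_GBM):
            xv_cal = vi_value(cal_refl, vi)
            xv_val = vi_value(val_refl, vi)
            m = fit_linear(xv_cal, cal_clb, feature=vi.name)
            r = validate(m, xv_val, val_clb)
            rows.append(
                {
                    "feature": f"{vi.name} (R{vi.band_a}, R{vi.band_b})",
                    "kind": "vegetation index",
                    "equation": m.equation,
                    "rc2": m.rc2,
                    "se": m.se,
                    "rv2": r.rv2,
                    "rrmse": r.rrmse,
                }
            )
    comparison = pd.DataFrame(rows)

    infl = influence_profile(
        winner, top_feat.wavelength, top_feat.scale_exponent,
        config.resolution_exponent,
    )
    cal_coefs, _, _ = cwt_matrix(
        cal_refl, winner, [top_feat.scale_exponent], config.resolution_exponent
    )
    mean_profile = cal_coefs[:, 0, :].mean(axis=0)
    position = classify_feature_position(mean_profile, top_feat.wavelength)
    regions = contiguous_regions(top_sets[winner])

    result = RunResult(
        config=config,
        dataset=dataset,
        scalograms=scalograms,
        top_sets=top_sets,
        ranking=ranking,
        occurrence=occ,
        winner=winner,
        models=models,
        comparison=comparison,
        subgroups=subgroups,
        influence=infl,
        position_class=position,
        regions=regions,
        failures=failures,
    )
    if config.output_dir:
        write_artifacts(result, Path(config.output_dir))
    return result


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir", None)  # hash the scientific config, not the location
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_artifacts(result: RunResult, outdir: Path) -> None:
    """Write all run artifacts as delimited text (deterministic content)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    manifest = {
        "package": "wavetrait",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "winner": result.winner,
        "position_class": result.position_class,
        "failures": result.failures,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    rank_df = pd.DataFrame(result.ranking.ranking, columns=["function", "best_rc2"])
    rank_df["optimal"] = rank_df["function"].isin(result.ranking.optimal)
    rank_df["poor"] = rank_df["function"].isin(result.ranking.poor)
    rank_df.to_csv(outdir / "ranking.csv", index=False, float_format="%.6f")
    result.ranking.family_summary.to_csv(
        outdir / "families.csv", index=False, float_format="%.6f"
    )
    result.occurrence.to_long_frame().to_csv(outdir / "occurrence.csv", index=False)

    tops = [
        {"function": fn, "rank": i + 1, "wavelength": f.wavelength,
         "scale_exponent": f.scale_exponent}
        for fn, feats in sorted(result.top_sets.items())
        for i, f in enumerate(feats)
    ]
    pd.DataFrame(tops).to_csv(outdir / "top_sets.csv", index=False)

    model_rows = []
    for model, report in result.models:
        f = model.feature
        model_rows.append(
            {
                "feature": f"{f.function} (W{f.wavelength}, S{f.scale_exponent})",
                "equation": model.equation,
                "rc2": round(model.rc2, 4),
                "se_kg_m2": round(model.se, 4),
                "n_cal": model.n_cal,
                "rv2": round(report.rv2, 4),
                "rrmse_pct": round(report.rrmse, 4),
                "n_val": report.n_val,
            }
        )
    pd.DataFrame(model_rows).to_csv(outdir / "models.csv", index=False)
    result.comparison.to_csv(outdir / "comparison.csv", index=False, float_format="%.6f")
    result.subgroups.to_csv(outdir / "subgroups.csv", index=False, float_format="%.6f")
    result.influence.to_frame().to_csv(
        outdir / "influence.csv", index=False, float_format="%.8g"
    )
    pd.DataFrame(
        [
            {"scale_exponent": s, "start_nm": a, "end_nm": b}
            for s, (a, b) in result.regions
        ]
    ).to_csv(outdir / "regions.csv", index=False)
    pd.DataFrame(
        [
            {"wavelength": wl, "rank": i + 1}
            for i, wl in enumerate(result.influence.influential)
        ]
    ).to_csv(outdir / "influential_wavelengths.csv", index=False)
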