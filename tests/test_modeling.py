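import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavetrait.cwt_engine import cwt_matrix
from wavetrait.modeling import (
    NDVI_BLEAF,
    RVI_GBM,
    VIDefinition,
    classify_feature_position,
    fit_linear,
    influence_profile,
    rrmse,
    subgroup_report,
    validate,
    vi_value,
)
from wavetrait.spectra_io import N_BANDS, WL_MIN, SpectralSample
from _oracles import brute_force_ols


class TestFitLinear:
    def test_exact_fit(self):
        x = np.array([1.0, 2, 3, 4])
        m = fit_linear(x, 2 * x + 1)
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.rc2 == pytest.approx(1.0)
        assert m.se == pytest.approx(0.0, abs=1e-12)
        assert m.equation == "Y = 2.000x+1.000"

    def test_matches_brute_force_sse_minimiser(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = 0.7 * x - 0.2 + rng.normal(0, 0.5, 30)
        m = fit_linear(x, y)
        s, i = brute_force_ols(x, y)
        assert m.slope == pytest.approx(s, abs=1e-3)
        assert m.intercept == pytest.approx(i, abs=1e-3)

    def test_too_small_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_linear([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRrmse:
    def test_worked_example(self):
        assert rrmse([1.0, 2, 3], [2.0, 2, 2]) == pytest.approx(40.8248, abs=1e-3)

    def test_perfect_prediction_is_zero(self):
        assert rrmse([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_common_positive_rescaling_invariance(self, c):
        P = np.array([0.1, 0.4, 0.2])
        O = np.array([0.2, 0.3, 0.25])
        assert rrmse(c * P, c * O) == pytest.approx(rrmse(P, O), rel=1e-9)

    def test_zero_mean_observation_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            rrmse([1.0, -1.0], [1.0, -1.0])


class TestValidate:
    def test_rv2_equals_rc2_on_the_calibration_set(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50)
        y = 0.3 * x + 0.1 + rng.normal(0, 0.2, 50)
        m = fit_linear(x, y)
        rep = validate(m, x, y)
        assert rep.rv2 == pytest.approx(m.rc2, abs=1e-12)

    def test_exact_model_on_identical_data(self):
        x = np.array([1.0, 2, 3])
        m = fit_linear(x, 2 * x + 0.5)
        rep = validate(m, x, 2 * x + 0.5)
        assert rep.rv2 == pytest.approx(1.0)
        assert rep.rrmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_predictions_defined_as_zero(self):
        m = fit_linear(np.array([1.0, 2, 3]), np.array([1.0, 2.1, 2.9]))
        m.slope = 0.0
        rep = validate(m, np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
        assert rep.rv2 == 0.0

    def test_empty_validation_rejected(self):
        m = fit_linear(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError, match="empty"):
            validate(m, np.array([]), np.array([]))


class TestVegetationIndices:
    def test_normalized_difference(self):
        refl = np.full(N_BANDS, 0.4)
        s = SpectralSample("a", refl)
        assert vi_value(s, NDVI_BLEAF) == pytest.approx(0.0)
        refl2 = refl.copy()
        refl2[NDVI_BLEAF.band_a - WL_MIN] = 0.3
        refl2[NDVI_BLEAF.band_b - WL_MIN] = 0.1
        assert vi_value(SpectralSample("b", refl2), NDVI_BLEAF) == pytest.approx(0.5)

    def test_simple_ratio(self):
        refl = np.full(N_BANDS, 0.1)
        refl[RVI_GBM.band_a - WL_MIN] = 0.2
        assert vi_value(SpectralSample("a", refl), RVI_GBM) == pytest.approx(2.0)

    def test_zero_denominator_rejected(self):
        refl = np.zeros(N_BANDS)
        with pytest.raises(ZeroDivisionError):
            vi_value(SpectralSample("a", refl), RVI_GBM)

    def test_off_grid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            VIDefinition("bad", 300, 565, "simple-ratio")


class TestSubgroups:
    def _model_and_data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y = 0.2 * x + 0.15 + rng.normal(0, 0.05, n)
        y = np.abs(y) + 0.01
        return fit_linear(x, y), x, y

    def test_single_subgroup_equals_overall(self):
        m, x, y = self._model_and_data()
        rep = subgroup_report(m, x, y, np.repeat("only", len(x)), "site")
        row = rep.subgroups.iloc[0]
        assert row["rv2"] == pytest.approx(rep.rv2)
        assert row["rrmse"] == pytest.approx(rep.rrmse)

    def test_mean_row_is_arithmetic_mean_of_subgroups(self):
        m, x, y = self._model_and_data()
        groups = np.where(np.arange(len(x)) % 2 == 0, "a", "b")
        rep = subgroup_report(m, x, y, groups, "variety")
        df = rep.subgroups
        body = df[(df["subgroup"] != "Mean") & ~df["flagged"]]
        mean_row = df[df["subgroup"] == "Mean"].iloc[0]
        assert mean_row["rv2"] == pytest.approx(body["rv2"].mean())
        assert mean_row["rrmse"] == pytest.approx(body["rrmse"].mean())

    def test_small_subgroup_flagged_and_suppressed(self):
        m, x, y = self._model_and_data(n=20)
        groups = np.array(["big"] * 18 + ["tiny"] * 2)
        rep = subgroup_report(m, x, y, groups, "site")
        tiny = rep.subgroups[rep.subgroups["subgroup"] == "tiny"].iloc[0]
        assert bool(tiny["flagged"]) and np.isnan(tiny["rv2"])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_homogeneous_halves_stay_near_overall(self, seed):
        m, x, y = self._model_and_data(seed=seed, n=400)
        groups = np.where(np.arange(len(x)) % 2 == 0, "a", "b")
        rep = subgroup_report(m, x, y, groups, "site")
        body = rep.subgroups[rep.subgroups["subgroup"].isin(["a", "b"])]
        assert np.all(np.abs(body["rv2"].to_numpy() - rep.rv2) < 0.12)


class TestInfluence:
    def test_matches_finite_difference_of_the_transform(self):
        prof = influence_profile("mexh", 1100, 5)
        rng = np.random.default_rng(9)
        f = np.clip(rng.normal(0.3, 0.05, N_BANDS), 0, 1)
        base = cwt_matrix(f[None], "mexh", [5])[0][0, 0, 1100 - WL_MIN]
        for wl in (1050, 1100, 1140):
            fp = f.copy()
            h = 1e-6
            fp[wl - WL_MIN] += h
            bumped = cwt_matrix(fp[None], "mexh", [5])[0][0, 0, 1100 - WL_MIN]
            assert (bumped - base) / h == pytest.approx(
                prof.sensitivity[wl - WL_MIN], rel=1e-6, abs=1e-9
            )

    def test_vanishes_beyond_the_scaled_support(self):
        prof = influence_profile("mexh", 1100, 3)
        # support +-8 at scale 2**3 = 64 nm half-width
        assert prof.sensitivity[1100 - WL_MIN + 80] == 0.0
        assert prof.sensitivity[1100 - WL_MIN - 80] == 0.0

    def test_symmetric_psi_gives_symmetric_profile(self):
        prof = influence_profile("mexh", 1100, 4)
        i = 1100 - WL_MIN
        for d in (1, 5, 20):
            assert prof.sensitivity[i - d] == pytest.approx(
                prof.sensitivity[i + d], rel=1e-9, abs=1e-12
            )


class TestPositionClass:
    def test_sine_root_is_zero_crossing(self):
        lam = np.arange(N_BANDS, dtype=float)
        profile = np.sin(2 * np.pi * (lam - (1000 - WL_MIN)) / 200.0)
        assert classify_feature_position(profile, 1000) == "zero-crossing"

    def test_parabola_vertex_is_peak(self):
        lam = np.arange(N_BANDS, dtype=float)
        profile = 1.0 - ((lam - (1200 - WL_MIN)) / 500.0) ** 2
        assert classify_feature_position(profile, 1200) == "peak"
        assert classify_feature_position(-profile, 1200) == "valley"

    def test_boundary_wavelength_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            classify_feature_position(np.ones(N_BANDS), 350)
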