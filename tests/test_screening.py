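import dataclasses

import numpy as np
import pytest

from wavetrait.cwt_engine import cwt_matrix
from wavetrait.screening import (
    FeatureSpec,
    Scalogram,
    contiguous_regions,
    occurrence_map,
    r2_matrix,
    rank_functions,
    scalogram_from_coefficients,
    scalogram_r2,
    top_fraction,
)
from wavetrait.spectra_io import (
    N_BANDS,
    Dataset,
    water_band_mask,
)
from wavetrait.wavelet_bank import evaluate_psi
from conftest import make_dataset


def _all_eligible_scalogram(r2):
    return Scalogram(
        function="mexh",
        scale_exponents=(3, 4, 5, 6, 7, 8),
        r2_all=r2,
        eligible=np.ones_like(r2, bool),
    )


class TestScalogram:
    def test_exact_linear_dependence_gives_r2_of_one(self):
        ds = make_dataset(n=10, seed=3)
        _, refl, _, _ = ds.to_arrays()
        coefs, _, _ = cwt_matrix(refl, "mexh", [4])
        x = coefs[:, 0, 1000 - 350]
        clb = 0.5 * (x - x.min()) + 0.05  # exact affine map, positive
        traits = [
            dataclasses.replace(t, clb=float(clb[i])) for i, t in enumerate(ds.traits)
        ]
        ds2 = Dataset(samples=ds.samples, traits=traits,
                      split={t.sample_id: "calibration" for t in traits})
        sg = scalogram_r2(ds2, "mexh", [4])
        assert sg.r2_all[0, 1000 - 350] == pytest.approx(1.0, abs=1e-12)

    def test_permuted_trait_has_no_strong_cell(self):
        ds = make_dataset(n=200, seed=11)
        _, refl, clb, _ = ds.to_arrays()
        rng = np.random.default_rng(42)
        coefs, boundary, _ = cwt_matrix(refl, "mexh")
        sg = scalogram_from_coefficients(
            coefs, rng.permutation(clb), "mexh", boundary
        )
        assert np.nanmax(sg.r2) < 0.15

    def test_insufficient_calibration_samples_rejected(self):
        ds = make_dataset(n=4)
        ds = Dataset(
            samples=ds.samples,
            traits=ds.traits,
            split={t.sample_id: ("calibration" if i < 2 else "validation")
                   for i, t in enumerate(ds.traits)},
        )
        with pytest.raises(ValueError, match="3 calibration"):
            scalogram_r2(ds, "mexh", [4])

    def test_zero_variance_cell_defined_as_zero(self):
        coefs = np.zeros((5, 1, N_BANDS))
        coefs[:, 0, 0] = [1, 2, 3, 4, 5]
        r2 = r2_matrix(coefs, np.array([1.0, 2, 3, 4, 5]))
        assert r2[0, 0] == pytest.approx(1.0)
        assert r2[0, 1] == 0.0

    def test_trait_affine_invariance(self):
        ds = make_dataset(n=20, seed=5)
        _, refl, clb, _ = ds.to_arrays()
        coefs, _, _ = cwt_matrix(refl, "mexh", [4, 5])
        a = r2_matrix(coefs, clb)
        b = r2_matrix(coefs, 3.7 * clb - 1.2)
        assert np.allclose(a, b, atol=1e-12)

    def test_psi_rescaling_leaves_r2_unchanged(self):
        ds = make_dataset(n=20, seed=6)
        _, refl, clb, _ = ds.to_arrays()
        sw = evaluate_psi("db7", 10)
        swr = dataclasses.replace(
            sw, psi=-2.0 * sw.psi, integrated_psi=-2.0 * sw.integrated_psi
        )
        a = r2_matrix(cwt_matrix(refl, sw, [5])[0], clb)
        b = r2_matrix(cwt_matrix(refl, swr, [5])[0], clb)
        assert np.allclose(a, b, atol=1e-12)


class TestTopFraction:
    def test_cardinality_is_ceiling_of_q_times_eligible(self):
        rng = np.random.default_rng(0)
        sg = _all_eligible_scalogram(rng.uniform(0, 1, (6, N_BANDS)))
        feats = top_fraction(sg, 0.01)
        assert len(feats) == 130  # ceil(0.01 * 12906)

    def test_unique_maximum_is_the_argmax(self):
        r2 = np.zeros((6, N_BANDS))
        r2[2, 1234 - 350] = 0.9
        sg = _all_eligible_scalogram(r2)
        feats = top_fraction(sg, q=1.0 / (6 * N_BANDS))
        assert feats == [FeatureSpec("mexh", 1234, 5)]

    def test_all_ties_resolved_by_scale_then_wavelength(self):
        sg = _all_eligible_scalogram(np.full((6, N_BANDS), 0.5))
        feats = top_fraction(sg, q=3.5 / (6 * N_BANDS))
        assert feats == [
            FeatureSpec("mexh", 350, 8),
            FeatureSpec("mexh", 351, 8),
            FeatureSpec("mexh", 352, 8),
            FeatureSpec("mexh", 353, 8),
        ]

    def test_masked_cells_are_never_selected(self):
        r2 = np.zeros((6, N_BANDS))
        r2[:, water_band_mask()] = 1.0
        r2[0, 900 - 350] = 0.2
        sg = Scalogram("mexh", (3, 4, 5, 6, 7, 8), r2,
                       np.broadcast_to(~water_band_mask(), (6, N_BANDS)))
        feats = top_fraction(sg, q=1.0 / int(sg.eligible.sum()))
        assert feats == [FeatureSpec("mexh", 900, 3)]

    def test_q_out_of_range_rejected(self):
        sg = _all_eligible_scalogram(np.zeros((6, N_BANDS)))
        with pytest.raises(ValueError):
            top_fraction(sg, 0.0)


class TestOccurrence:
    def test_single_function_counts_equal_indicator(self):
        feats = [FeatureSpec("db7", 1100, 5), FeatureSpec("db7", 1101, 5)]
        occ = occurrence_map({"db7": feats})
        assert occ.counts.sum() == 2
        assert occ.counts[2, 1100 - 350] == 1

    def test_identical_sets_reach_the_function_count(self):
        feats = [FeatureSpec("x", 1000, 8)]
        occ = occurrence_map({f"f{i}": list(feats) for i in range(108)})
        assert occ.counts.max() == 108
        assert occ.counts.sum() == 108

    def test_disjoint_sets_and_conservation(self):
        sets = {
            "a": [FeatureSpec("a", 900, 3)],
            "b": [FeatureSpec("b", 901, 4), FeatureSpec("b", 902, 4)],
        }
        occ = occurrence_map(sets)
        assert occ.counts[occ.counts > 0].max() == 1
        assert occ.counts.sum() == sum(len(v) for v in sets.values())


class TestRanking:
    def test_single_high_performer_is_the_only_optimal(self):
        best = {f"f{i}": 0.60 for i in range(9)}
        best["winner"] = 0.90
        r = rank_functions(best)
        assert r.optimal == {"winner"}
        assert r.poor == set()

    def test_zero_spread_yields_no_outliers(self):
        r = rank_functions({f"f{i}": 0.7 for i in range(6)})
        assert r.optimal == set() and r.poor == set()

    def test_monotone_values_without_outliers(self):
        # quartile oracle: values 0.50..0.59, Q1=0.5225, Q3=0.5675,
        # fences 0.455 / 0.635 lie outside the data range
        best = {f"f{i}": 0.50 + 0.01 * i for i in range(10)}
        r = rank_functions(best)
        assert r.q1 == pytest.approx(0.5225)
        assert r.q3 == pytest.approx(0.5675)
        assert r.optimal == set() and r.poor == set()
        values = [v for _, v in r.ranking]
        assert values == sorted(values, reverse=True)

    def test_too_few_functions_rejected(self):
        with pytest.raises(ValueError, match="4 functions"):
            rank_functions({"a": 0.5, "b": 0.6, "c": 0.7})


class TestRegions:
    def test_adjacency_definition(self):
        feats = [FeatureSpec("f", 1100, 7), FeatureSpec("f", 1101, 7),
                 FeatureSpec("f", 1103, 7)]
        assert contiguous_regions(feats) == [(7, (1100, 1101)), (7, (1103, 1103))]

    def test_empty_set(self):
        assert contiguous_regions([]) == []

    def test_one_cell_per_scale_gives_singletons(self):
        feats = [FeatureSpec("f", 1000 + s, s) for s in range(3, 9)]
        regions = contiguous_regions(feats)
        assert len(regions) == 6
        assert all(a == b for _, (a, b) in regions)
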