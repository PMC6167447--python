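import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavetrait.spectra_io import (
    N_BANDS,
    WAVELENGTHS,
    SpectraIOError,
    SpectralSample,
    apply_water_band_mask,
    assign_split,
    read_spectra_table,
    read_trait_table,
    water_band_mask,
    write_spectra_table,
    write_trait_table,
)
from conftest import make_dataset


class TestWaterBandMask:
    def test_masked_band_count_is_252(self):
        # 61 + 161 + 30 bands inside the three closed windows
        assert water_band_mask().sum() == 252

    def test_constant_spectrum_zeroed_inside_windows_only(self):
        s = apply_water_band_mask(SpectralSample("a", np.full(N_BANDS, 0.5)))
        assert s.reflectance[1400 - 350] == 0.0
        assert s.reflectance[1300 - 350] == 0.5
        assert s.reflectance[1790 - 350] == 0.0
        assert s.reflectance[2470 - 350] == 0.5

    def test_zero_spectrum_is_fixed_point(self):
        s = apply_water_band_mask(SpectralSample("a", np.zeros(N_BANDS)))
        assert np.all(s.reflectance == 0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_masking_is_idempotent(self, seed):
        refl = np.random.default_rng(seed).uniform(0, 1, N_BANDS)
        once = apply_water_band_mask(SpectralSample("a", refl))
        twice = apply_water_band_mask(once)
        assert np.array_equal(once.reflectance, twice.reflectance)
        assert np.array_equal(once.mask, twice.mask)


class TestTables:
    def test_reader_writer_roundtrip(self, tmp_path, rng):
        ds = make_dataset(n=3)
        spath, tpath = tmp_path / "spec.csv", tmp_path / "traits.csv"
        write_spectra_table(ds.samples, spath)
        write_trait_table(ds.traits, tpath)
        samples = read_spectra_table(spath)
        traits = read_trait_table(tpath)
        assert [s.sample_id for s in samples] == [s.sample_id for s in ds.samples]
        for a, b in zip(samples, ds.samples):
            assert np.allclose(a.reflectance, b.reflectance, atol=1e-12)
        assert [t.sample_id for t in traits] == [t.sample_id for t in ds.traits]
        assert all(a.clb == pytest.approx(b.clb) for a, b in zip(traits, ds.traits))

    def test_missing_band_names_the_column(self, tmp_path):
        ds = make_dataset(n=2)
        path = tmp_path / "spec.csv"
        write_spectra_table(ds.samples, path)
        df = pd.read_csv(path).drop(columns=["1200"])
        df.to_csv(path, index=False)
        with pytest.raises(SpectraIOError, match="1200"):
            read_spectra_table(path)

    def test_out_of_range_reflectance_names_the_cell(self, tmp_path):
        ds = make_dataset(n=2)
        path = tmp_path / "spec.csv"
        ds.samples[1].reflectance[777 - 350] = 1.7
        write_spectra_table(ds.samples, path)
        with pytest.raises(SpectraIOError, match=r"s001.*777"):
            read_spectra_table(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        ds = make_dataset(n=2)
        path = tmp_path / "spec.csv"
        ds.samples[1].sample_id = ds.samples[0].sample_id
        write_spectra_table(ds.samples, path)
        with pytest.raises(SpectraIOError, match="duplicate"):
            read_spectra_table(path)

    def test_band_columns_reordered_to_canonical_grid(self, tmp_path):
        ds = make_dataset(n=1)
        path = tmp_path / "spec.csv"
        write_spectra_table(ds.samples, path)
        df = pd.read_csv(path)
        shuffled = df[["sample_id"] + [str(w) for w in WAVELENGTHS[::-1]]]
        shuffled.to_csv(path, index=False)
        (sample,) = read_spectra_table(path)
        assert np.allclose(sample.reflectance, ds.samples[0].reflectance, atol=1e-12)


class TestSplit:
    def test_split_counts_match_experiment_sizes(self):
        ds = make_dataset(n=24, n_experiments=8)
        ds = assign_split(ds, {"exp2", "exp4", "exp5", "exp7", "exp8"})
        roles = pd.Series(ds.split)
        sizes = pd.Series({t.sample_id: t.experiment_id for t in ds.traits})
        expected = sizes.isin({"exp2", "exp4", "exp5", "exp7", "exp8"}).sum()
        assert (roles == "calibration").sum() == expected

    def test_empty_calibration_set_puts_all_in_validation(self):
        ds = assign_split(make_dataset(n=6), set())
        assert set(ds.split.values()) == {"validation"}

    def test_unknown_experiment_id_rejected(self):
        with pytest.raises(SpectraIOError, match="nope"):
            assign_split(make_dataset(n=6), {"nope"})

    def test_split_never_separates_an_experiment(self):
        ds = assign_split(make_dataset(n=30, n_experiments=5), {"exp1", "exp3"})
        roles = {}
        for t in ds.traits:
            roles.setdefault(t.experiment_id, set()).add(ds.split[t.sample_id])
        assert all(len(r) == 1 for r in roles.values())
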