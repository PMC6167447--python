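import numpy as np
import pytest

from wavetrait.spectra_io import (
    N_BANDS,
    Dataset,
    SpectralSample,
    TraitRecord,
    apply_water_band_mask,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def random_masked_spectrum(rng):
    refl = np.clip(rng.normal(0.3, 0.1, N_BANDS), 0.0, 1.0)
    return apply_water_band_mask(SpectralSample("spec0", refl))


def make_dataset(n=12, n_experiments=3, seed=0, clb=None):
    """Small hand-rolled dataset with smooth random spectra."""
    from scipy.ndimage import gaussian_filter1d

    r = np.random.default_rng(seed)
    base = np.clip(
        0.3 + 0.1 * gaussian_filter1d(r.standard_normal((n, N_BANDS)), 40, axis=1),
        0.0,
        1.0,
    )
    samples = [
        apply_water_band_mask(SpectralSample(f"s{i:03d}", base[i])) for i in range(n)
    ]
    if clb is None:
        clb = r.uniform(0.05, 0.3, n)
    traits = [
        TraitRecord(
            sample_id=f"s{i:03d}",
            clb=float(clb[i]),
            experiment_id=f"exp{i % n_experiments + 1}",
            site=f"site{i % 2 + 1}",
            variety=f"var{i % 2 + 1}",
            sampling_date=f"200{4 + i % 2}-04-{10 + i % 10:02d}",
            growth_stage="before" if i % 2 == 0 else "after",
        )
        for i in range(n)
    ]
    return Dataset(samples=samples, traits=traits)
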