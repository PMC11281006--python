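import numpy as np
import pytest

from specfluor.io import SpectraMatrix
from specfluor.synthetic import SyntheticConfig, generate_dataset


def make_matrix(values, lo_nm=400, tag="reflectance", species=None, group=None):
    """SpectraMatrix from a raw 2-D array on a contiguous grid starting at lo_nm."""
    values = np.atleast_2d(np.asarray(values, float))
    n, m = values.shape
    return SpectraMatrix(
        wavelengths=np.arange(lo_nm, lo_nm + m),
        values=values,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        species=None if species is None else np.asarray(species, dtype=object),
        group=None if group is None else np.asarray(group, dtype=object),
        transform_tag=tag,
    )


def smooth_random_spectra(n_samples, rng, lo_nm=400, hi_nm=2400):
    """Random smooth in-(0,1) spectra: sums of broad Gaussians on the grid."""
    wl = np.arange(lo_nm, hi_nm + 1)
    values = np.full((n_samples, wl.size), 0.25)
    for _ in range(6):
        centre = rng.uniform(lo_nm, hi_nm, size=n_samples)
        width = rng.uniform(60, 300, size=n_samples)
        amp = rng.uniform(-0.1, 0.15, size=n_samples)
        values += amp[:, None] * np.exp(
            -0.5 * ((wl[None, :] - centre[:, None]) / width[:, None]) ** 2
        )
    return make_matrix(np.clip(values, 0.01, 0.95), lo_nm=lo_nm)


@pytest.fixture(scope="session")
def small_dataset():
    """A 48-leaf synthetic dataset shared by read-only tests."""
    config = SyntheticConfig(n_samples=48, seed=11)
    spectra, fluor = generate_dataset(config)
    return config, spectra, fluor
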