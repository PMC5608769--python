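import numpy as np
import pytest

from msilipid.annotate import build_library
from msilipid.imzml_io import MSIDataset, Spectrum
from msilipid.phantom import generate, three_region_spec


@pytest.fixture(scope="session")
def pos_library():
    return build_library("positive")


@pytest.fixture(scope="session")
def neg_library():
    return build_library("negative")


@pytest.fixture(scope="session")
def small_phantom():
    """24x24 three-region phantom with moderate noise."""
    spec = three_region_spec(24, 24, noise_cv=0.2, seed=11)
    return generate(spec)


@pytest.fixture()
def tiny_dataset():
    """Four pixels on a 2x2 grid, three peaks each."""
    spectra = [
        Spectrum(
            mz=np.array([400.0, 500.0, 600.0]),
            intensity=np.array([10.0, 20.0, 30.0]) * (i + 1),
            pixel=pixel,
        )
        for i, pixel in enumerate([(1, 1), (2, 1), (1, 2), (2, 2)])
    ]
    return MSIDataset(spectra=spectra, grid=(2, 2), polarity="positive")


def make_dataset(peak_lists, grid=None, polarity="positive"):
    """Build a dataset from {(x, y): (mz_list, intensity_list)}."""
    spectra = [
        Spectrum(mz=np.asarray(mz, dtype=float), intensity=np.asarray(inten, dtype=float),
                 pixel=pixel)
        for pixel, (mz, inten) in peak_lists.items()
    ]
    if grid is None:
        grid = (max(p[0] for p in peak_lists), max(p[1] for p in peak_lists))
    return MSIDataset(spectra=spectra, grid=grid, polarity=polarity)
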