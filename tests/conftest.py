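import warnings

import numpy as np
import pytest

from voxeldecode import BandGrid, BoldSeries, build_band_grid


@pytest.fixture(scope="session")
def default_grid() -> BandGrid:
    """The 32-band 0.003-0.313 Hz grid at TR 2 s (Nyquist warning silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_band_grid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def make_series(values, tr=2.0, **kw) -> BoldSeries:
    return BoldSeries(values=np.asarray(values, dtype=float), tr_seconds=tr, **kw)
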