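import numpy as np
import pytest

from hemianet.recording import RegionRecording
from hemianet.preprocess import segment
from hemianet.connectivity import epoch_spectra, imaginary_coherence


@pytest.fixture()
def rng():
    # fresh fixed-seed generator per test: draws do not depend on which
    # other tests ran or in what order
    return np.random.default_rng(12345)


def band_icoh(data: np.ndarray, fs: float, band: str) -> np.ndarray:
    """Convenience: band icoh matrix straight from a channels x samples array."""
    rec = RegionRecording(data, fs, [f"ch{i}" for i in range(data.shape[0])])
    return imaginary_coherence(epoch_spectra(segment(rec)), band).values


@pytest.fixture(scope="session")
def random_symmetric():
    """Factory for random symmetric zero-diagonal weight matrices."""

    def make(k: int, seed: int) -> np.ndarray:
        r = np.random.default_rng(seed)
        w = r.random((k, k))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        return w

    return make
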