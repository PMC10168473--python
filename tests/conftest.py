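import numpy as np
import pytest

from daric.genome import BinnedGenome, CompartmentTrack, OEMatrix, PISTrack


@pytest.fixture
def genome2():
    """Two small chromosomes; chrA has a short last bin (70 kb at 50 kb)."""
    return BinnedGenome(("chrA", "chrB"), (1_070_000, 800_000), 50_000)


@pytest.fixture
def genome1():
    return BinnedGenome(("chr1",), (1_250_000,), 50_000)  # 25 bins


def make_track(genome, values, cls=PISTrack, **kw):
    return cls(genome, np.asarray(values, dtype=float), **kw)


def plaid_matrix(e, strength=0.8):
    """Noise-free plaid O/E matrix from a latent profile."""
    e = np.asarray(e, dtype=float)
    finite = np.isfinite(e)
    vals = np.exp(strength * np.outer(np.where(finite, e, 0), np.where(finite, e, 0)))
    valid = np.outer(finite, finite)
    vals[~valid] = 0.0
    return vals, valid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_oe(genome1, rng):
    """Random symmetric all-valid O/E matrix plus balanced compartments."""
    n = genome1.n_bins_chrom("chr1")
    m = rng.uniform(0.1, 3.0, size=(n, n))
    m = (m + m.T) / 2
    oe = OEMatrix("chr1", m, np.ones((n, n), dtype=bool))
    labels = np.array(([1] * 12) + ([-1] * 12) + [0], dtype=np.int8)
    comps = CompartmentTrack(genome1, labels)
    return oe, comps
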