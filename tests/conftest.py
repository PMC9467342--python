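import numpy as np
import pytest

from mareyscape.io_maps import MareyMap
from mareyscape.marey_fit import Landscape, fit_marey


def make_map(bp, cm, length=None, species="sp", chromosome="chr1", **kw):
    bp = np.asarray(bp, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if length is None:
        length = float(bp.max())
    ids = np.array([f"m{i}" for i in range(bp.shape[0])])
    return MareyMap(species, chromosome, bp, cm, ids, float(length), **kw)


def make_landscape(rates, window_size=1e5, species="sp", chromosome="chr1"):
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[0]
    starts = np.arange(n) * window_size
    ends = starts + window_size
    return Landscape(
        species=species,
        chromosome=chromosome,
        chromosome_length=n * window_size,
        starts=starts,
        ends=ends,
        rate=rates,
        window_size=window_size,
    )


@pytest.fixture
def linear_map():
    """100 cM over 50 Mb, 100 evenly spaced markers."""
    return make_map(np.linspace(0, 50e6, 100), np.linspace(0, 100, 100), 50e6)


@pytest.fixture
def linear_fit(linear_map):
    return fit_marey(linear_map, span=0.3)
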