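import numpy as np
import pytest

from medrefugia.popgen import GeoAlignment, Sample
from medrefugia.rasters import Raster


@pytest.fixture
def toy_alignment() -> GeoAlignment:
    """Six samples, four haplotypes, three localities."""
    seqs = {
        "s1": ("ACGTACGTAC", "L1", 36.0, 3.0),
        "s2": ("ACGTACGTAC", "L1", 36.0, 3.0),
        "s3": ("ACGTACGTAC", "L2", 38.0, 5.0),
        "s4": ("ACGAACGTAC", "L2", 38.0, 5.0),
        "s5": ("ACGAACGTAT", "L3", 40.0, 8.0),
        "s6": ("TCGAACGTAT", "L3", 40.0, 8.0),
    }
    return GeoAlignment([Sample(k, *v) for k, v in seqs.items()])


@pytest.fixture
def small_raster() -> Raster:
    vals = np.arange(25, dtype=float).reshape(5, 5)
    return Raster(vals, xll=0.0, yll=40.0, cellsize=1.0)


def make_geoalignment(seqs, lats=None, lons=None, locs=None) -> GeoAlignment:
    n = len(seqs)
    lats = lats or [35.0 + i for i in range(n)]
    lons = lons or [0.0 + i for i in range(n)]
    locs = locs or [f"L{i}" for i in range(n)]
    return GeoAlignment([
        Sample(f"s{i}", seqs[i], locs[i], lats[i], lons[i])
        for i in range(n)])
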