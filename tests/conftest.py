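import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rxfire import RecordSet, Source

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from rxfire._proj import LocalEquirectangular
from rxfire.landcover import LandCoverGrid


def make_records(rows, source=Source.FINN, **provenance):
    """Build a RecordSet from (id, lon, lat, date, area[, burn_type]) tuples."""
    recs = []
    for row in rows:
        rec = {
            "id": str(row[0]),
            "longitude": float(row[1]),
            "latitude": float(row[2]),
            "date": pd.Timestamp(row[3]),
            "area": float(row[4]),
        }
        rec["burn_type"] = row[5] if len(row) > 5 else "UNKNOWN"
        recs.append(rec)
    df = pd.DataFrame(recs)
    return RecordSet(df, source, provenance)


def uniform_grid(code, n=50, cell=30.0, lon0=-82.0, lat0=31.0, year=2019):
    """A square raster filled with one land-cover class, centered at (lon0, lat0)."""
    crs = LocalEquirectangular(lon0, lat0)
    half = n * cell / 2.0
    return LandCoverGrid(
        classes=np.full((n, n), code, dtype=np.int16),
        x0=-half, y0=-half, cell_size=cell, crs=crs, year=year,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230524)
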