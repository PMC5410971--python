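import numpy as np
import pytest

from rangecoder.formats import OccurrenceRecord, OperationalUnit
from rangecoder.geometry import GeoPoint, PolygonDef


@pytest.fixture
def unit_square() -> PolygonDef:
    return PolygonDef("square", [(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def grid_fixture():
    """1,000 seeded uniform points over a 10x10 polygon grid, with the
    closed-form cell-index assignment as the oracle."""
    from rangecoder.synthgen import (
        gen_global_localities,
        gen_polygon_grid,
        grid_cell_index,
        localities_to_records,
    )

    extent = (-180.0, 180.0, -90.0, 90.0)
    units = gen_polygon_grid(10, 10, extent)
    table = gen_global_localities(1000, seed=42, n_species=25, extent=extent)
    records = localities_to_records(table)
    oracle = {
        i: grid_cell_index(r.point.lon, r.point.lat, 10, 10, extent)
        for i, r in enumerate(records)
    }
    return records, units, oracle


def make_records(rows) -> list[OccurrenceRecord]:
    """rows: iterable of (species, lon, lat)."""
    return [
        OccurrenceRecord(sp, GeoPoint(lon, lat), i + 2)
        for i, (sp, lon, lat) in enumerate(rows)
    ]


def square_unit(name, x0, y0, x1, y1, band=None) -> OperationalUnit:
    return OperationalUnit(
        name, PolygonDef(name, [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]), band
    )
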