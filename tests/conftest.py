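import dataclasses

import numpy as np
import pandas as pd
import pytest

from coastpop.geodata import AdminLayer, GridSpec, Raster
from coastpop.synthgen import SceneConfig, generate_scene


def small_config(n: int = 128, seed: int = 7, **kwargs) -> SceneConfig:
    """A scaled-down scene config sharing the default study conditions."""
    spec = GridSpec(n, n, origin_x=0.0, origin_y=n * 100.0, cell_size=100.0,
                    crs_tag="synthetic-albers")
    base = dict(
        spec=spec,
        seed=seed,
        n_provinces=2,
        n_counties=16,
        townships_per_county=6,
        n_settlements=6,
        total_population=600_000.0,
    )
    base.update(kwargs)
    return dataclasses.replace(SceneConfig(), **base)


@pytest.fixture(scope="session")
def small_scene():
    """128x128 scene used by most integration-level tests."""
    return generate_scene(small_config())


@pytest.fixture(scope="session")
def tiny_scene():
    """64x64 scene for cheap smoke paths."""
    return generate_scene(small_config(n=64, seed=3, n_counties=8,
                                       townships_per_county=4, n_settlements=4,
                                       total_population=200_000.0))


def toy_admin(census: dict[int, float], n_cells_per_unit: int = 1,
              cell_size: float = 100.0) -> tuple[AdminLayer, Raster]:
    """A 1-row grid of single-township counties (one county per township),
    all under one province — handy for hand-computable metric tests.

    Returns (admin, labels_spec_raster_template)."""
    unit_ids = sorted(census)
    n = len(unit_ids) * n_cells_per_unit
    spec = GridSpec(1, n, origin_x=0.0, origin_y=cell_size, cell_size=cell_size,
                    crs_tag="toy")
    labels = np.zeros((1, n), dtype=np.int64)
    records = [dict(unit_id=1, level="province", parent_id=0,
                    census_pop=float(sum(census.values())),
                    area_km2=n * spec.cell_area_km2)]
    for i, tid in enumerate(unit_ids):
        labels[0, i * n_cells_per_unit:(i + 1) * n_cells_per_unit] = tid
        county_id = 100 + i
        records.append(dict(unit_id=county_id, level="county", parent_id=1,
                            census_pop=float(census[tid]),
                            area_km2=n_cells_per_unit * spec.cell_area_km2))
        records.append(dict(unit_id=tid, level="township", parent_id=county_id,
                            census_pop=float(census[tid]),
                            area_km2=n_cells_per_unit * spec.cell_area_km2))
    admin = AdminLayer(Raster(spec, labels, 0), pd.DataFrame.from_records(records))
    return admin, Raster(spec, np.zeros((1, n)))
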