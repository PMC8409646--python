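import numpy as np
import pytest

import pitchshapes as ps


@pytest.fixture(scope="session")
def square_polygon():
    return ps.make_canonical_shape("square", scale=10.0)


@pytest.fixture(scope="session")
def square_image(square_polygon):
    return ps.rasterize(square_polygon)


@pytest.fixture(scope="session")
def ngon64_polygon():
    # regular 64-gon, circumradius 10 m = 50 px at the default resolution
    return ps.make_canonical_shape("regular_ngon", scale=10.0, n=64)


@pytest.fixture(scope="session")
def ngon64_image(ngon64_polygon):
    return ps.rasterize(ngon64_polygon)


def random_hull(rng, n_points=10, box=30.0):
    return ps.convex_hull(rng.uniform(0.0, box, size=(n_points, 2)))


@pytest.fixture(scope="session")
def small_collection():
    """16-image scale-varied collection (2 templates x 2 scales x 4)."""
    items, manifest = ps.benchmark_collection(
        templates=("4-4-2", "3-5-2"),
        scales=(1.0, 2.0),
        images_per_class=4,
        seed=99,
    )
    return items, manifest


@pytest.fixture(scope="session")
def small_table(small_collection):
    items, _ = small_collection
    return ps.descriptor_table(items)
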