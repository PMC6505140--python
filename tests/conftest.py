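import numpy as np
import pytest

import pshquant as pq


@pytest.fixture
def thresholds():
    return pq.ColorThresholds()


@pytest.fixture
def halo_colony():
    """Circular ring radius 30, halo to 45 px, half coverage."""
    return pq.ColonySpec(center=(80, 80), ring_outer_radii=(30, 30),
                         ring_thickness=5, halo_extent=15, halo_coverage=0.5)


@pytest.fixture
def random_colony_specs():
    """200 random colony geometries spanning the renderer's parameter space."""
    rng = np.random.default_rng(123)
    specs = []
    for _ in range(200):
        a, b = rng.uniform(20, 40, size=2)
        specs.append(pq.ColonySpec(
            center=(80, 80), ring_outer_radii=(float(a), float(b)),
            ring_thickness=float(rng.uniform(3, 0.5 * min(a, b))),
            halo_extent=float(rng.uniform(0, 25)),
            halo_coverage=float(rng.uniform(0, 1)),
            ring_irregularity=float(rng.uniform(0, 0.2))))
    return specs


@pytest.fixture
def full_plate():
    """96-colony plate with varying halo coverage plus its rendered output."""
    rng = np.random.default_rng(7)
    colonies = {
        (gr, gc): pq.ColonySpec(
            center=(50, 50), ring_outer_radii=(22, 20), ring_thickness=5,
            halo_extent=12, halo_coverage=float(rng.uniform(0, 1)),
            ring_irregularity=0.05)
        for gr in range(8) for gc in range(12)}
    spec = pq.PlateSpec(cell_size=100, margin=20, colonies=colonies)
    image, truths, classmap = pq.render_plate(spec, seed=3)
    return spec, image, truths, classmap
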