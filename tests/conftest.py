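import numpy as np
import pytest

from adiporisk.morphometry import CalibratedRaster, measure_image
from adiporisk.synthetic import AdipoImageSpec, generate_adipose_image


@pytest.fixture(scope="session")
def hundred_cell_image():
    """A 1024 µm² canvas with 100 ground-truthed adipocytes at 0.5 µm/px."""
    spec = AdipoImageSpec(n_cells=100, seed=3)
    raster, objects = generate_adipose_image(spec)
    return spec, raster, objects


@pytest.fixture(scope="session")
def hundred_cell_measured(hundred_cell_image):
    spec, raster, objects = hundred_cell_image
    kept, rejected = measure_image(
        CalibratedRaster(raster, spec.microns_per_pixel))
    return kept, rejected


@pytest.fixture(scope="session")
def sparse_image():
    """Widely spaced cells (45 µm septa) so CD68 rims never overlap
    neighbouring annuli."""
    spec = AdipoImageSpec(width_px=2000, height_px=2000, n_cells=30, seed=6,
                          membrane_thickness_um=45.0)
    raster, objects = generate_adipose_image(spec)
    return spec, raster, objects


def match_to_truth(measured, truth):
    """Pair each measured object with the nearest ground-truth centroid."""
    pairs = []
    for m in measured:
        best = min(truth, key=lambda o: (o.centroid_xy[0] - m.centroid_xy[0]) ** 2
                   + (o.centroid_xy[1] - m.centroid_xy[1]) ** 2)
        pairs.append((m, best))
    return pairs


@pytest.fixture(scope="session")
def compartment_model():
    from adiporisk.composition import train_compartment_classifier
    from adiporisk.synthetic import TEXTURE_KINDS, make_texture_patch

    rng = np.random.default_rng(0)
    patches = [(make_texture_patch(kind, rng=rng), kind)
               for kind in TEXTURE_KINDS for _ in range(60)]
    return train_compartment_classifier(patches, seed=0)
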