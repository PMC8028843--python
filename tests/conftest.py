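import numpy as np
import pytest

import riceyield as ry


@pytest.fixture(scope="session")
def default_scene():
    """Default study layout: 13 lines x 3 replicates, 176 bands."""
    return ry.simulate_field(ry.SimConfig(), seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """A cheap 3-line scene for geometry/IO tests."""
    config = ry.SimConfig(
        n_lines=3, n_replicates=3, plot_size_px=10, class_counts=(1, 1, 1)
    )
    return ry.simulate_field(config, seed=3)


@pytest.fixture(scope="session")
def default_samples(default_scene):
    scene, fieldmap, _ = default_scene
    library = ry.ReferenceSpectraLibrary.from_truth(scene)
    mask = ry.sam_classify(scene, library)
    rois = ry.select_plot_rois(mask, fieldmap, margin_px=2)
    return ry.sample_pixels(rois, scene, fieldmap, n=30, seed=7)


@pytest.fixture(scope="session")
def feature_tables(default_scene, default_samples):
    _, fieldmap, _ = default_scene
    with_lodging = ry.build_feature_table(
        default_samples, fieldmap, with_lodging=True
    )
    without = ry.build_feature_table(
        default_samples, fieldmap, with_lodging=False
    )
    return with_lodging, without


def make_fieldmap(class_sizes, n_replicates=3, plot_px=4):
    """A field map with the requested class sizes, built through the
    simulator so geometry/validation stay consistent."""
    n_lines = sum(class_sizes)
    config = ry.SimConfig(
        n_lines=n_lines,
        n_replicates=n_replicates,
        n_bands=8,
        plot_size_px=plot_px,
        gap_px=1,
        class_counts=tuple(class_sizes),
    )
    _, fieldmap, _ = ry.simulate_field(config, seed=11)
    return fieldmap


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
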