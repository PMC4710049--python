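import numpy as np
import pytest

from xyspot import SceneConfig, generate_scene, render_images


@pytest.fixture(scope="session")
def small_scene():
    """50 well-separated cells on a 400x400 ellipse, noise-free, sparse spots.

    The low spot mean keeps same-gene spots spatially resolvable, so exact
    ground-truth recovery (one detected spot per true signal) is well-posed.
    """
    cfg = SceneConfig(
        image_height=400,
        image_width=400,
        n_cells=50,
        min_nucleus_separation=24.0,
        nucleus_radius_mean=4.0,
        nucleus_radius_sd=0.3,
        spots_per_expressing_cell_mean=0.05,
        class_proportions={"no_signal": 0.3, "x_only": 0.3, "y_only": 0.3, "mixed": 0.1},
        noise_sd=0.0,
        seed=44,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene_channels(small_scene):
    return render_images(small_scene)


def paint_nuclei(scene) -> np.ndarray:
    """Ground-truth nucleus label image (discs, labels = generator cell ids)."""
    h, w = scene.config.image_height, scene.config.image_width
    labels = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, ((r, c), rad) in enumerate(zip(scene.nuclei_centers, scene.nuclei_radii), start=1):
        labels[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = i
    return labels
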