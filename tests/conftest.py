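import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srclem import synthetic_data as sd
from srclem.transform import AffineTransform2D

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


REGISTERED_SEM_PIXEL = 4.0

#: axis-aligned ground-truth affine (pure scale) so the rendered SEM image
#: is already on the world grid -- i.e. "registered" by construction
REGISTERED_AFFINE = AffineTransform2D.from_components(
    scale=1.0 / REGISTERED_SEM_PIXEL)


@pytest.fixture(scope="session")
def quiet_optics():
    """Noise-free optics without beads: isolates the podosome structures."""
    return sd.OpticsSpec(bead_count=0, noise_scale=0.0)


@pytest.fixture(scope="session")
def single_podosome(quiet_optics):
    """One noise-free podosome, no filament mat: clean geometry recovery."""
    cluster = sd.ClusterSpec(n_podosomes=1, field_size_xy=(7000.0, 7000.0),
                             ventral_filament_density=0.0)
    scene = sd.generate_scene(cluster, quiet_optics, sd.SEMSpec(), seed=2)
    stack = sd.render_lm_stack(scene, quiet_optics)
    return scene, stack, quiet_optics


@pytest.fixture(scope="session")
def pair_scene():
    """Associated podosome pair (noisy LM, registered-frame SEM)."""
    cluster = sd.ClusterSpec(n_podosomes=2, field_size_xy=(8000.0, 8000.0),
                             associated_pairs=((0, 1),))
    optics = sd.OpticsSpec(bead_count=3, noise_scale=1.0)
    semspec = sd.SEMSpec(sem_pixel=REGISTERED_SEM_PIXEL)
    scene = sd.generate_scene(cluster, optics, semspec, seed=21,
                              affine_true=REGISTERED_AFFINE)
    stack = sd.render_lm_stack(scene, optics)
    sem_img = sd.render_sem(scene, semspec)
    return scene, stack, sem_img, optics, semspec
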