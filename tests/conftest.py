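import numpy as np
import pandas as pd
import pytest

from lungsig.synthetic import GenerativeSpec, generate_cohort, generate_immune
from lungsig.volumes import LesionVolume


@pytest.fixture(scope="session")
def study_spec() -> GenerativeSpec:
    """Default study conditions with exact class/stage counts."""
    return GenerativeSpec(exact_counts=True, seed=1)


@pytest.fixture(scope="session")
def study_cohort(study_spec) -> pd.DataFrame:
    return generate_cohort(study_spec)


@pytest.fixture(scope="session")
def study_immune(study_spec, study_cohort):
    features, truth = generate_immune(study_cohort, study_spec)
    return features, truth


def make_sphere_volume(
    radius_mm: float = 6.0,
    shape=(32, 32, 32),
    spacing=(1.0, 1.0, 1.0),
    inside_hu: float = 50.0,
    outside_hu: float = -800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LesionVolume:
    """Analytic sphere phantom used as a simple lesion fixture."""
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                        indexing="ij")
    centre = [(s - 1) * sp / 2 for s, sp in zip(shape, spacing)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre)))
    mask = r <= radius_mm
    image = np.where(mask, inside_hu, outside_hu).astype(float)
    if noise_sd > 0:
        image += np.random.default_rng(seed).normal(0, noise_sd, shape)
    return LesionVolume(image=image, spacing=spacing, mask=mask)


@pytest.fixture()
def sphere_volume() -> LesionVolume:
    return make_sphere_volume()
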