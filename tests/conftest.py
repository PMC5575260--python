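import numpy as np
import pytest

from evraman.pipeline import preprocess_dataset
from evraman.simulate import Band, ClassSpec, GeneratorConfig, default_config, generate_dataset


def small_cohort_config(seed: int, separation: float = 1.0, n_per_class: int = 16,
                        noise_sd: float = 0.01, baseline_scale: float = 0.0,
                        donor_effect_sd: float = 0.05,
                        step: float = 2.0) -> GeneratorConfig:
    """A reduced three-class cohort for fast cross-validation tests.

    `separation` linearly interpolates each class's lipid weights between the
    pooled mean mixture (0 = identical classes) and the default contrasts (1);
    class-specific extra bands are likewise scaled.
    """
    base = default_config(seed=seed)
    mean_w = np.mean([c.lipid_weights for c in base.classes], axis=0)
    classes = []
    for c in base.classes:
        w = mean_w + separation * (c.lipid_weights - mean_w)
        extra = [Band(b.center, b.fwhm, b.amplitude * separation, b.shape)
                 for b in c.extra_bands if b.amplitude * separation > 0]
        classes.append(ClassSpec(c.name, w, extra, n_donors=2,
                                 n_spectra=n_per_class))
    return GeneratorConfig(classes=classes, seed=seed, noise_sd=noise_sd,
                           baseline_scale=baseline_scale,
                           donor_effect_sd=donor_effect_sd, step=step)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (3 classes, 50/105/43 spectra), seed 1."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    d, truth = default_cohort
    dp, info = preprocess_dataset(d)
    return dp, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
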