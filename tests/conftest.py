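import numpy as np
import pytest

from advcad import phantom as ph


def tiny_config(seed: int = 3, n_patients: int = 16) -> ph.PhantomConfig:
    """A miniature cohort config for fast unit tests (64x52 images)."""
    return ph.PhantomConfig(
        n_patients=n_patients,
        positive_fraction=0.3,
        image_height=64,
        image_width=52,
        lesion=ph.LesionParams(
            radius_range=(3.0, 6.0),
            peak_contrast_range=(0.16, 0.32),
            spicule_count_range=(2, 5),
            spicule_length_range=(2.0, 5.0),
        ),
        split_fractions=(0.6, 0.2, 0.2),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    return ph.generate_cohort(tiny_config())


def gan_test_config(seed: int = 4) -> ph.PhantomConfig:
    """Balanced miniature cohort sized so GAN phase-C epochs hold several
    batches (the schedule's sliding-window margin needs them)."""
    cfg = tiny_config(seed=seed, n_patients=40)
    cfg.positive_fraction = 0.5
    return cfg


@pytest.fixture(scope="session")
def gan_cohort():
    return ph.generate_cohort(gan_test_config())


@pytest.fixture(scope="session")
def desk_cohort():
    """The study-scale cohort (100 patients at 128x104)."""
    return ph.generate_cohort(ph.PhantomConfig(n_patients=100, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
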