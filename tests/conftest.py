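import numpy as np
import pytest

from soyield import PlantLatent, TrialConfig, render_plant_views
from soyield.segmentation import PlantImage, PlantMask


@pytest.fixture(scope="session")
def rendered_plant():
    """One rendered 7-view plant with known truth masks and scale."""
    return render_plant_views(
        PlantLatent(area_px=2500), seed=7, canvas=160, sample_id="fixture"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_view(rng, h=32, w=32, fg_frac=0.6):
    """A random RGB view with a random (non-empty) mask."""
    img = PlantImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8).astype(np.uint8))
    mask = rng.random((h, w)) < fg_frac
    if not mask.any():
        mask[h // 2, w // 2] = True
    return img, PlantMask(mask)


def small_table_config(seed=0, signals=None, n_noise=5, n_varieties=100, reps=3):
    """A compact two-year single-treatment trial for statistical tests."""
    return TrialConfig(
        n_varieties=n_varieties,
        n_reps=reps,
        treatments=("sole",),
        varieties_per_year={2022: n_varieties, 2023: n_varieties},
        planted_signals=signals if signals is not None else {"sig": 0.8},
        n_noise_features=n_noise,
        n_outliers={2022: 0, 2023: 0},
        seed=seed,
    )
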