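import numpy as np
import pytest

from gliaplex.panel import STATE_NAMES, default_panel
from gliaplex.synth import (
    CohortParams,
    generate_intensity_dataset,
    place_scene,
    render_channel_stack,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def astro_markers(panel):
    return panel.phenotypic("astrocyte")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest astrocyte cohort with the default study conditions."""
    params = CohortParams(
        cell_type="astrocyte", n_subjects_per_group=4, cells_per_subject=150, seed=7
    )
    profiles, truth = generate_intensity_dataset(params)
    return params, profiles, truth


def _render_one_field(params, n_cells, panel):
    profiles, _ = generate_intensity_dataset(params)
    sub = profiles.iloc[:n_cells].reset_index(drop=True)
    rng = np.random.default_rng(params.seed)
    states = np.array([STATE_NAMES.index(s) for s in sub["state"]])
    lesions, cents = place_scene(params, states=states, rng=rng)
    stack, via, truth = render_channel_stack(
        sub, lesions, cents, params, panel, {"field_id": "test_field"}
    )
    return sub, lesions, stack, via, truth


@pytest.fixture(scope="session")
def noise_free_field(panel):
    """A rendered astrocyte field with zero background and zero pixel noise."""
    params = CohortParams(
        cell_type="astrocyte",
        n_subjects_per_group=1,
        cells_per_subject=30,
        background=(0.0, 0.0),
        pixel_noise_sd=0.0,
        seed=5,
    )
    return _render_one_field(params, 30, panel)


@pytest.fixture(scope="session")
def noisy_field(panel):
    """A rendered field with the default background drift and pixel noise."""
    params = CohortParams(
        cell_type="astrocyte", n_subjects_per_group=1, cells_per_subject=35, seed=6
    )
    return _render_one_field(params, 35, panel)
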