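import numpy as np
import pytest

import phenolscreen as ps


@pytest.fixture(scope="session")
def plate_8x12():
    """A rendered 8x12 plate with known densities and its layout/params."""
    layout = ps.synthdata.layout_for_grid(
        8, 12, strains=[f"s{i:02d}" for i in range(92)]
    )
    rng = np.random.default_rng(42)
    densities = rng.uniform(200.0, 1200.0, size=(8, 12))
    params = ps.synthdata.RenderParams(seed=42)
    image = ps.synthdata.render_plate_image(densities, layout, params)
    return {
        "layout": layout,
        "densities": densities,
        "params": params,
        "image": image,
        "true_rows": params.margin_px + params.grid_pitch_px * np.arange(8),
        "true_cols": params.margin_px + params.grid_pitch_px * np.arange(12),
    }


@pytest.fixture(scope="session")
def small_screen():
    """A 200-strain simulated screen with planted sensitive/resistant effects."""
    truth, tables = ps.synthdata.simulate_screen(
        n_strains=200,
        frac_sensitive=0.1,
        frac_resistant=0.05,
        noise_cv=0.15,
        n_replicates=3,
        seed=7,
    )
    return truth, tables
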