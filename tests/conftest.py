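"""Shared fixtures: synthetic frames reused across test modules.

Heavier frames are session-scoped so rendering happens once.
"""

import numpy as np
import pytest

from dropev import FrameConfig, generate_frame


@pytest.fixture(scope="session")
def packed_frame():
    """One packed-monolayer frame at reduced resolution, with truth."""
    cfg = FrameConfig(pixel_size_um=2.0, seed=42)
    frame, truth = generate_frame(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def sparse_frame():
    """100 isolated droplets (dart placement) in a small field."""
    cfg = FrameConfig(
        frame_width_um=700.0, frame_height_um=700.0, pixel_size_um=1.0,
        placement="dart", n_droplets=100, droplet_diameter_cv=0.0,
        bead_lambda=0.5, seed=7,
    )
    frame, truth = generate_frame(cfg)
    return cfg, frame, truth


@pytest.fixture()
def toy_droplet_table():
    """Hand-built droplet table.

    48 beadless background droplets (raw 9/11), one bright bead-free
    stray (raw 40), one bright droplet with a DAPI bead (raw 60), one
    dim droplet with a DAPI bead (raw 11).
    """
    import pandas as pd

    n = 51
    raw = np.array([9.0, 11.0] * 24 + [40.0, 60.0, 11.0])
    dapi = np.zeros(n, dtype=int)
    dapi[[49, 50]] = 1
    return pd.DataFrame({
        "label": np.arange(1, n + 1),
        "frame_id": ["f"] * n,
        "centroid_row_px": np.zeros(n),
        "centroid_col_px": np.zeros(n),
        "x_um": np.zeros(n),
        "y_um": np.zeros(n),
        "diameter_um": np.full(n, 28.0),
        "area_px": np.full(n, 600),
        "on_border": [False] * n,
        "fitc_mean_raw": raw,
        "fitc_mean_corrected": np.nan,
        "n_beads_dapi": dapi,
        "n_beads_cy5": np.zeros(n, dtype=int),
        "positive": [False] * n,
        "excluded": [False] * n,
    })


def pytest_configure(config):
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True)
    settings.load_profile("deterministic")
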