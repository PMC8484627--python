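import numpy as np
import pandas as pd
import pytest

from sceneaffect import ALL_BINS, ObserverSpec, synth_choice_session


def random_polyline(rng: np.random.Generator, max_points: int = 12) -> np.ndarray:
    """A random valid polyline: distinct consecutive points, coords in [0, 100]."""
    n = int(rng.integers(2, max_points + 1))
    while True:
        pts = rng.uniform(0, 100, size=(n, 2))
        if not np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            return pts


@pytest.fixture(scope="session")
def cell_manifest() -> pd.DataFrame:
    """A minimal stimulus manifest: 20 images per design cell (480 ids)."""
    return pd.DataFrame(
        [
            {
                "image_id": f"{b}_{i:02d}",
                "length_class": b.length_class,
                "angularity_class": b.angularity_class,
                "orientation_class": b.orientation_class,
            }
            for b in ALL_BINS
            for i in range(20)
        ]
    )


@pytest.fixture(scope="session")
def small_gumbel_trials(cell_manifest) -> pd.DataFrame:
    """One simulated 12-participant choice session (Gumbel rule)."""
    return synth_choice_session(cell_manifest, ObserverSpec(), n_participants=12, seed=42)
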