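import numpy as np
import pytest

import ecoreserve as er


@pytest.fixture(scope="session")
def small_stack():
    """64x64 landscape with derived covariates (session-cached)."""
    cfg = er.LandscapeConfig(grid_shape=(64, 64), seed=7)
    return er.derive_standard_layers(er.generate_env_stack(cfg))


@pytest.fixture(scope="session")
def niche():
    return er.TrueNiche()


@pytest.fixture(scope="session")
def occurrences(small_stack, niche):
    return er.sample_presences(small_stack, niche, 150, seed=11)


@pytest.fixture(scope="session")
def fitted_ensemble(small_stack, occurrences):
    """A small but realistic multi-round ensemble fit (session-cached)."""
    reduced, _ = er.collinearity_filter(small_stack, occurrences.records)
    cfg = er.EnsembleConfig(n_rounds=3, seed=5)
    return reduced, er.fit_ensemble(reduced, occurrences, cfg)


def moran_i(grid: np.ndarray) -> float:
    """Brute-force Moran's I with rook (lag-1) neighbours."""
    z = grid - grid.mean()
    num = 0.0
    w = 0
    nr, nc = grid.shape
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < nr and c2 < nc:
                    num += 2 * z[r, c] * z[r2, c2]
                    w += 2
    return (len(z.ravel()) / w) * num / (z ** 2).sum()
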