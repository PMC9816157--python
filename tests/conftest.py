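import numpy as np
import pytest

from efgrelax.core import Configuration


def random_neutral_config(seed: int, n: int = 64, box: float = 12.0,
                          min_sep: float = 0.8) -> Configuration:
    """Random +-1e configuration with a minimum pair separation so that
    lattice sums are well conditioned."""
    rng = np.random.default_rng(seed)
    pos = []
    while len(pos) < n:
        cand = rng.uniform(0.0, box, 3)
        if pos:
            dr = np.asarray(pos) - cand
            dr -= box * np.round(dr / box)
            if np.min(np.linalg.norm(dr, axis=1)) < min_sep:
                continue
        pos.append(cand)
    charges = np.tile([1.0, -1.0], n // 2)
    return Configuration(np.asarray(pos), charges, box)


def rocksalt_config(n_side: int = 4, spacing: float = 2.0) -> Configuration:
    axis = np.arange(n_side) * spacing
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                    -1).reshape(-1, 3)
    parity = (grid.sum(axis=1) / spacing).astype(int) % 2
    charges = np.where(parity == 0, 1.0, -1.0)
    return Configuration(grid, charges, n_side * spacing)


@pytest.fixture
def neutral_config():
    return random_neutral_config(1)


@pytest.fixture
def rocksalt():
    return rocksalt_config()
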