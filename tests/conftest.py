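import numpy as np
import pytest

from lipidfes import synthetic as syn


@pytest.fixture(scope="session")
def small_membrane():
    """16-lipid-per-leaflet noiseless fixture with full ledger."""
    spec = syn.ToyMembraneSpec(lipids_per_leaflet=16, seed=7)
    system, traj, views, ledger = syn.generate_membrane_fixture(spec)
    return spec, system, traj, views, ledger


@pytest.fixture(scope="session")
def default_membrane():
    """Default-size (64/leaflet) fixture, contact ledger included."""
    spec = syn.ToyMembraneSpec(seed=3)
    system, traj, views, ledger = syn.generate_membrane_fixture(spec)
    return spec, system, traj, views, ledger


def brute_force_pair_distances(a, b, box):
    """Minimum-image oracle with an explicit image search over ±1 shifts."""
    out = []
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    for pa in a:
        for pb in b:
            d = min(np.linalg.norm(pa - (pb + s * box)) for s in shifts)
            out.append(d)
    return np.array(out)
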