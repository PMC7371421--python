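import numpy as np
import pytest

from bklinker.traj import Topology, Trajectory


def make_traj(coords, names=None, elements=None, resids=None, resnames=None,
              chains=None, segclass=None, box=500.0, dt_ns=0.05):
    """Build a Trajectory from raw coordinates with simple defaults.

    ``coords`` is (frames, atoms, 3) or (atoms, 3) for a single frame.
    By default every atom is a CA carbon of its own GLY residue on chain A.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    names = names if names is not None else ["CA"] * n
    elements = elements if elements is not None else ["C"] * n
    resids = resids if resids is not None else list(range(1, n + 1))
    resnames = resnames if resnames is not None else ["GLY"] * n
    chains = chains if chains is not None else ["A"] * n
    segclass = segclass if segclass is not None else ["protein"] * n
    top = Topology(names, elements, resids, resnames, chains, segclass,
                   [12.0] * n)
    nf = coords.shape[0]
    box_arr = np.full((nf, 3), box) if np.isscalar(box) else np.asarray(box)
    return Trajectory(top, coords, box_arr, np.arange(nf) * dt_ns)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def make_trajectory():
    return make_traj
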