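import numpy as np
import pytest

from sgmd import forcefield, groups, lattice, protocols

PLANAR_GROUPS = [
    "p1", "p2", "pm", "pg", "cm", "pmm", "pmg", "pgg", "cmm",
    "p4", "p4m", "p4g", "p3", "p3m1", "p31m", "p6", "p6m",
]

# general-position multiplicities from the standard wallpaper-group tables
PLANAR_MULTIPLICITY = {
    "p1": 1, "p2": 2, "pm": 2, "pg": 2, "cm": 4, "pmm": 4, "pmg": 4,
    "pgg": 4, "cmm": 8, "p4": 4, "p4m": 8, "p4g": 8, "p3": 3,
    "p3m1": 6, "p31m": 6, "p6": 6, "p6m": 12,
}


@pytest.fixture(scope="session", params=PLANAR_GROUPS)
def planar_group(request):
    return groups.load_group(request.param, 2)


@pytest.fixture(scope="session")
def sg127():
    return groups.load_group(127, 3)


def small_state(group_name, dim=2, n=2, density=0.4, seed=3, radius=2,
                temperature=0.0, **kw):
    return protocols.build_initial_state(
        group_name, n, density, dimension=dim, seed=seed,
        image_radius=radius, temperature=temperature, **kw
    )


def brute_force_cell_energy(state):
    """Independent oracle: expand every explicit particle and sum
    unordered unit-cell pairs plus half of each cell-image interaction."""
    cell = forcefield.ghost_positions(state)
    n_img = state.images.count
    per_particle = cell.reshape(-1, n_img, state.dimension)
    root = per_particle[:, state.images.zero_index, :]
    root_ids = {
        i * n_img + state.images.zero_index for i in range(len(root))
    }
    E = 0.0
    for a in range(len(root)):
        for b in range(a + 1, len(root)):
            r = float(np.linalg.norm(root[a] - root[b]))
            E += forcefield.lj_pair(r, state.lj)[0]
    for a in range(len(root)):
        for j in range(len(cell)):
            if j in root_ids:
                continue
            r = float(np.linalg.norm(root[a] - cell[j]))
            E += 0.5 * forcefield.lj_pair(r, state.lj)[0]
    return E
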