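"""Shared random-instance builder for PAF tests."""

import numpy as np


def random_paf_instance(rng, n_species=50, n_members=4, n_cells=40, occupancy=0.3):
    pools = {}
    for i in range(n_species):
        cells = frozenset(int(c) for c in np.flatnonzero(rng.random(n_cells) < occupancy))
        if cells:
            pools[f"sp{i}"] = cells
    members = [f"m{j}" for j in range(n_members)]
    exceed = {
        (sp, m): frozenset(c for c in cs if rng.random() < 0.35)
        for sp, cs in pools.items()
        for m in members
    }
    return pools, exceed, members, n_cells
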