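import numpy as np
import pytest

import froikit as fk


@pytest.fixture(scope="session")
def small_grid():
    """16^3 grid at 4 mm, centered on the origin."""
    return fk.mni_grid((16, 16, 16), 4.0)


@pytest.fixture(scope="session")
def origin_blob():
    return [fk.BlobSpec("R", (0.0, 0.0, 0.0))]


@pytest.fixture(scope="session")
def origin_space(small_grid, origin_blob):
    """Hypothesis space for the origin blob, built from an independent
    batch of 20 simulated subjects so downstream tests never reuse the
    subjects the space was defined on."""
    cohort = fk.generate_cohort(fk.CohortConfig(n_nt=20, n_asd=0), seed=5)
    maps = [even for _, even, _, _ in fk.simulate_cohort_maps(
        cohort, origin_blob, fk.NoiseSpec(sd=1.0), small_grid, seed=777)]
    return fk.extract_hypothesis_space(fk.group_rfx_tmap(maps), "R",
                                       (0.0, 0.0, 0.0))


def flood_fill_components(data, connectivity):
    """Brute-force BFS connected components of a boolean 3-D array."""
    data = np.asarray(data, dtype=bool)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(data.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(data)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if any(c < 0 or c >= s for c, s in zip(w, data.shape)):
                    continue
                if data[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)
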