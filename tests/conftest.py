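import numpy as np
import pytest

import connfp as cf


@pytest.fixture
def atlas6() -> cf.RegionAtlas:
    return cf.RegionAtlas(
        labels=("A.l", "B.l", "C.l", "A.r", "B.r", "C.r"),
        hemispheres=("l", "l", "l", "r", "r", "r"),
    )


@pytest.fixture
def small_cohort() -> cf.SimulatedCohort:
    """6 regions, 3+3 subjects, no planted effect."""
    spec = cf.SimCohortSpec(
        m=6, voxels_per_region=4, samples_per_voxel=500, n_per_group=(3, 3), seed=7
    )
    return cf.generate_cohort(spec)


@pytest.fixture
def effect_cohort() -> cf.SimulatedCohort:
    """8 regions, 6+6 subjects, one strong hyper-connectivity effect in group2."""
    base = tuple(3.0 if j == 5 else 0.5 for j in range(8))
    spec = cf.SimCohortSpec(
        m=8,
        voxels_per_region=10,
        n_per_group=(6, 6),
        baseline_concentration=base,
        effects=(cf.PlantedEffect(seed_node=2, target=5, factor=3.0, group="group2"),),
        seed=11,
    )
    return cf.generate_cohort(spec)


def brute_force_fingerprint(counts: np.ndarray, seed: int) -> np.ndarray:
    """Independent oracle: normalize each positive-total voxel, then average."""
    rows = []
    for row in counts:
        total = row.sum()
        if total > 0:
            rows.append(row / total)
    w = np.mean(rows, axis=0)
    w[seed] = 0.0
    return w
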