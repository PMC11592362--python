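"""Shared fixtures: small parcellations and synthetic cohorts built in memory."""

import numpy as np
import pytest

from connscreen import (
    CohortSpec,
    SubsampleConfig,
    compute_connectivity_tensor,
    generate_cohort,
)
from connscreen.atlas import ParcellationMap


@pytest.fixture
def four_roi_map() -> ParcellationMap:
    """2 networks x 2 hemispheres, one ROI each."""
    return ParcellationMap(
        [1, 2, 3, 4],
        ["LH_NetA", "LH_NetB", "RH_NetA", "RH_NetB"],
        ["L", "L", "R", "R"],
    )


@pytest.fixture
def six_roi_map() -> ParcellationMap:
    """2 networks, 3 ROIs each, one per hemisphere."""
    return ParcellationMap(
        [1, 2, 3, 4, 5, 6],
        ["LH_NetA"] * 3 + ["RH_NetB"] * 3,
        ["L"] * 3 + ["R"] * 3,
    )


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small null cohort spec used across modules (2 networks x 3 ROIs, 4+4)."""
    return CohortSpec(
        n_asd=4,
        n_td=4,
        networks=["LH_NetA", "RH_NetB"],
        rois_per_network=3,
        run_condition_lengths=[
            {"baseline": 44, "semantic": 36, "pragmatic": 36},
            {"baseline": 40, "semantic": 32, "pragmatic": 32},
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    cohort, pmap = generate_cohort(tiny_spec)
    return cohort, pmap


@pytest.fixture(scope="session")
def tiny_tensor(tiny_cohort):
    cohort, pmap = tiny_cohort
    cfg = SubsampleConfig(m=30, reps=20, seed=7)
    return compute_connectivity_tensor(cohort, pmap, cfg), pmap


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
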