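"""Shared fixtures.

The expensive fixture (``reference_runs``) runs the full-size scheme once per
test session: 10 replicates, each sharing one stage-1 run across seven
stage-2 branches.  All quantitative assertions draw on it; tolerances combine
the documented absolute bands with three across-replicate standard errors.
"""

from __future__ import annotations

import numpy as np
import pytest

from cryosim.experiment import (
    ReplicateResult,
    build_scenario,
    run_replicates_shared,
    scenario_label,
)
from cryosim.pedigree import FEMALE, MALE, Pedigree
from cryosim.scheme import SchemeConfig

MASTER_SEED = 20260920
N_REPLICATES = 10


def make_random_pedigree(
    rng: np.random.Generator,
    n_founders: int = 8,
    n_generations: int = 3,
    per_generation: int = 12,
) -> Pedigree:
    """Random discrete-generation pedigree for oracle comparisons."""
    ped = Pedigree()
    nm = max(n_founders // 2, 1)
    nf = n_founders - nm
    none = np.full(nm, -1, dtype=np.int64)
    zeros = np.zeros(nm)
    ped.add_cohort(0, MALE, none, none, zeros, zeros, zeros, zeros, zeros, 0.6)
    none = np.full(nf, -1, dtype=np.int64)
    zeros = np.zeros(nf)
    ped.add_cohort(0, FEMALE, none, none, zeros, zeros, zeros, zeros, zeros, 0.4)
    for g in range(1, n_generations):
        males = ped.males(g - 1)
        females = ped.females(g - 1)
        k = per_generation
        km = max(k // 3, 1)
        for sex, n in ((MALE, km), (FEMALE, k - km)):
            sires = males[rng.integers(0, len(males), n)]
            dams = females[rng.integers(0, len(females), n)]
            z = np.zeros(n)
            ped.add_cohort(g, sex, sires, dams, z, z, z, z, z, 0.5)
    # fill F so that diagonals are consistent where needed
    from cryosim.pedigree import kinship_pair

    memo: dict = {}
    for i in range(len(ped)):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        ped.f[i] = 0.0 if s < 0 else kinship_pair(ped, s, d, memo)
    return ped


@pytest.fixture(scope="session")
def scheme_config() -> SchemeConfig:
    return SchemeConfig()


@pytest.fixture(scope="session")
def reference_scenarios() -> list:
    return [
        build_scenario("b1"),
        build_scenario("b3", w_b=0.0),
        build_scenario("b3"),
        build_scenario("b3", w_b=1.0),
        build_scenario("b3", fraction=0.8),
        build_scenario("d1"),
        build_scenario("d2"),
        build_scenario("d3"),
    ]


@pytest.fixture(scope="session")
def reference_runs(
    scheme_config, reference_scenarios
) -> dict[str, list[ReplicateResult]]:
    """Full-size replicates of the reference scenarios (shared stage 1)."""
    return run_replicates_shared(
        reference_scenarios, scheme_config, N_REPLICATES, MASTER_SEED
    )


def mean_and_se(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))
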