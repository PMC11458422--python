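"""Shared fixtures.

``tiny_world`` is a seconds-scale simulated world for mechanical tests;
``desk_study`` is the session-scoped desk-profile study (5 replicates,
all model/scenario cells, r_pc in {0.2, 0.5, 0.8, 1.0}) shared by the
acceptance-level checks so the expensive simulation runs once.
"""

import numpy as np
import pytest

from crossblup import pipeline
from crossblup.config import SimConfig


def tiny_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2, chrom_length_cm=100.0, n_markers=400, n_qtl=40,
        hist_size_start=120, hist_size_end=80, hist_gens_constant=30,
        hist_gens_decline=20, hist_gens_final=10,
        breed_founder_males=8, breed_founder_females=30,
        breed_founders_disjoint=False,
        expansion_generations=8, expansion_cap=200,
        recent_males=8, recent_females=40, recent_generations=5,
        cross_generations=(3, 4, 5), cross_sires_per_cohort=15,
        cross_dams_per_sire=2,
        geno_ab_per_cohort=40, geno_b_dams_per_cohort=20,
        profile="desk",
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    return pipeline.build_world(tiny_cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def desk_study():
    """The desk-profile study grid; r_pc = 1.0 rides along for the
    dispersion calibration check (levels share each replicate's world)."""
    plan = pipeline.StudyPlan(
        config=SimConfig.desk(),
        r_pc_levels=(0.2, 0.5, 0.8, 1.0),
        cells=pipeline.MODEL_CELLS,
        n_replicates=5,
        base_seed=1,
    )
    results, structure = pipeline.run_study(plan)
    return plan, results, structure


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int,
                    p_unknown: float = 0.0):
    """Random valid pedigree (1-based, 0 = unknown), parents before
    offspring; optionally leaves some parents unknown past the founders."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        if p_unknown and rng.random() < p_unknown:
            continue
        sire[i] = rng.integers(1, i + 1)
        dam[i] = rng.integers(1, i + 1)
        if dam[i] == sire[i]:
            dam[i] = 0
    return sire, dam
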