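import numpy as np
import pytest

import trajmix
from trajmix.cohort import (
    LongitudinalCohort,
    Region,
    RegionManifest,
    SubjectRecord,
    VisitRecord,
)


def toy_manifest(n: int = 3) -> RegionManifest:
    return RegionManifest(
        Region(f"r{i:02d}", f"Synthetic region {i}", "projection", "deep") for i in range(n)
    )


def make_cohort(values, ages, manifest=None, sex=None, apoe4=None) -> LongitudinalCohort:
    """Build a cohort from per-subject lists of (age -> region values)."""
    manifest = manifest or toy_manifest(len(values[0][0]))
    rids = manifest.region_ids
    subjects = []
    for i, (subj_vals, subj_ages) in enumerate(zip(values, ages)):
        visits = [
            VisitRecord(f"s{i}", float(a), dict(zip(rids, v)))
            for v, a in zip(subj_vals, subj_ages)
        ]
        subjects.append(
            SubjectRecord(
                f"s{i}",
                sex[i] if sex else 0,
                apoe4[i] if apoe4 else 0,
                {},
                visits,
            )
        )
    return LongitudinalCohort(subjects, manifest)


@pytest.fixture(scope="session")
def separable_cohort():
    """Two well-separated clusters, 30 subjects, 4 regions."""
    cfg = trajmix.well_separated_config(30, 4, 2, seed=1)
    cohort, truth = trajmix.simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def separable_fit(separable_cohort):
    """A relabelled fit of the separable cohort (shared across tests)."""
    cohort, truth, _ = separable_cohort
    zc = trajmix.zscore_regions(cohort)
    chains = trajmix.relabel_chains(
        trajmix.fit_mixture(zc, 2, init_labels=truth.true_label,
                            mcmc=trajmix.McmcConfig(n_iter=1000, seed=2))
    )
    return zc, truth, chains
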