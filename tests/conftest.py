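import numpy as np
import pytest

from rlmvpa.model_fitting import fit_hierarchical_em
from rlmvpa.rl_models import ModelSpec
from rlmvpa.synthetic_data import CohortConfig, generate_cohort

# EM settings used wherever a cohort fit is needed inside the time budget;
# dev benchmarks showed recovery indistinguishable from the full defaults.
FAST_EM = dict(restarts=5, warm_restarts=1, max_iter=12, tol=3e-3)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, 2 networks, 40 voxels — cheap but full-structure cohort."""
    cfg = CohortConfig(n_subjects=8, n_networks=2, n_voxels=40, striatum_network_index=0)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def behavior_cohort_60():
    """Behavior-only cohort at the default population size (neural kept tiny)."""
    cfg = CohortConfig(n_subjects=60, n_networks=1, n_voxels=2)
    return generate_cohort(cfg, seed=23)


@pytest.fixture(scope="session")
def em_fit_60(behavior_cohort_60):
    """One shared hierarchical fit of the generating spec at n=60."""
    return fit_hierarchical_em(
        behavior_cohort_60.trial_records, ModelSpec(True, True), seed=0, **FAST_EM
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
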