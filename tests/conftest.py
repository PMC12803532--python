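import numpy as np
import pytest

import cardiotraj as ct
from cardiotraj.synthetic import CohortConfig, HazardConfig


def separated_config(n=600, seed=7, n_groups=3):
    """Three well-separated flat groups (>= 5 residual SDs apart)."""
    curves = np.zeros((n_groups, 2, 2))
    curves[:, 0, 0] = np.linspace(40.0, 90.0, n_groups)
    curves[:, 1, 0] = np.linspace(0.6, 1.6, n_groups)
    prev = {3: (0.5, 0.3, 0.2)}.get(n_groups,
                                    tuple(np.full(n_groups, 1.0 / n_groups)))
    return CohortConfig(
        n_participants=n,
        group_prevalences=prev,
        group_curves=tuple(map(lambda g: tuple(map(tuple, g)), curves)),
        residual_sd=((3.0, 0.05),) * n_groups,
        hazards=HazardConfig(hf_log_hr=(0.0,) * n_groups,
                             death_log_hr=(0.0,) * n_groups,
                             subtype_probs=((0.5, 0.3, 0.2),) * n_groups),
        seed=seed,
    )


@pytest.fixture(scope="session")
def separated_cohort():
    cfg = separated_config()
    visits, covariates, survival, truth = ct.generate_cohort(cfg)
    return {"config": cfg, "visits": visits, "covariates": covariates,
            "survival": survival, "truth": truth}


@pytest.fixture(scope="session")
def separated_fit(separated_cohort):
    model = ct.fit_trajectories(separated_cohort["visits"], k_max=10,
                                restarts=4, seed=11)
    return model


@pytest.fixture(scope="session")
def derivation_fit():
    """Default derivation-style cohort and full-scale fit (shared: it is slow)."""
    cfg = ct.derivation_config(n_participants=750, seed=1)
    visits, covariates, survival, truth = ct.generate_cohort(cfg)
    model = ct.fit_trajectories(visits, k_max=20, restarts=20, seed=2)
    return {"config": cfg, "visits": visits, "covariates": covariates,
            "survival": survival, "truth": truth, "model": model}
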