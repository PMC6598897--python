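import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_dataset():
    """1 subject, 2 visits, 3 markers; anchor m0 missing at visit 2."""
    from adprogress.data import LongitudinalDataset

    obs = pd.DataFrame(
        {
            "subject_id": ["a"] * 3 + ["a"] * 2,
            "time_years": [0.0] * 3 + [1.0] * 2,
            "marker": ["m0", "m1", "m2", "m1", "m2"],
            "value": [1.0, 2.0, 3.0, 2.5, 3.5],
        }
    )
    cov = pd.DataFrame({"subject_id": ["a"], "age_bl": [70.0], "sex": ["female"],
                        "apoe4": ["carrier"], "dx_bl": ["CN"]})
    dx = pd.DataFrame({"subject_id": ["a", "a"], "time_years": [0.0, 1.0], "dx": ["CN", "MCI"]})
    return LongitudinalDataset(obs, cov, dx, marker_panel=["m0", "m1", "m2"])


def make_gaussian_cohort(
    n=60, p=2, seed=0, times=(0.0, 0.5, 1.0, 2.0), sigma=0.05, omega=None, family="JMM",
    v_diag=None, sigma_delta=0.5,
):
    """Percentile-scale cohort without covariate effects, for recovery tests."""
    from adprogress.cohort import CohortConfig, generate_cohort

    markers = tuple(f"m{k}" for k in range(p))
    beta = np.column_stack([np.linspace(0.3, 0.5, p), np.zeros(p), np.zeros(p), np.zeros(p)])
    cfg = CohortConfig(
        n_subjects=n, markers=markers, visit_times=tuple(times), family=family,
        beta=beta, sigma=np.full(p, sigma), omega=omega,
        v_diag=v_diag, sigma_delta=sigma_delta,
        anchor_marker="m0", mcar_rate=0.0, dropout_hazard=0.0,
        emit_scale="percentile", with_amyloid=False, seed=seed,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_jmm_fit():
    """One shared small JMM fit reused across stage-1 tests."""
    from adprogress.stage1 import MCMCConfig, ModelSpec, fit_model

    dataset, truth = make_gaussian_cohort(n=40, p=2, seed=3)
    config = MCMCConfig(iterations=240, warmup=120, chains=2, thin=3, seed=5)
    spec = ModelSpec("JMM", ("m0", "m1"))
    draws = fit_model(spec, dataset, config)
    return dataset, truth, draws
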