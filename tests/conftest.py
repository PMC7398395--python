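"""Shared fixtures: published models, small simulated cohorts, toy configs."""

from dataclasses import replace

import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from hairpk import (
    CohortSpec,
    RandomEffectSpec,
    atv_final_model,
    rtv_final_model,
    simulate_cohort,
)
from hairpk.io import to_analysis_frame


@pytest.fixture(scope="session")
def atv_model():
    return atv_final_model()


@pytest.fixture(scope="session")
def rtv_model():
    return rtv_final_model()


@pytest.fixture(scope="session")
def small_cohort():
    """n=40 study-structure cohort (censoring on), both analytes."""
    return simulate_cohort(CohortSpec(n_subjects=40, seed=11))


@pytest.fixture(scope="session")
def atv_frame(small_cohort):
    cov, obs = small_cohort
    return to_analysis_frame(cov, obs, "ATV")


@pytest.fixture(scope="session")
def iov_model(atv_model):
    """ATV model with inter-occasion variability on the hair fraction.

    The per-occasion log-normal effect gives the likelihood two active
    random-effect dimensions per subject — the configuration used to
    exercise the conditional-mode and quadrature machinery.
    """
    return replace(
        atv_model,
        random_effects=RandomEffectSpec(
            omega2_cl=1.04, omega2_k12=0.45, omega2_vc=0.50, omega2_frac_iov=0.1
        ),
    )


def iov_frame(iov_model, n_subjects=6, seed=0):
    """Simulate a small cohort under an IOV-active model."""
    cov, obs = simulate_cohort(
        CohortSpec(
            n_subjects=n_subjects,
            seed=seed,
            models={"ATV": iov_model, "RTV": rtv_final_model()},
            censoring=False,
        )
    )
    return to_analysis_frame(cov, obs, "ATV")
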