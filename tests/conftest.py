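import pytest

from hernia_markov import (
    LifeExpectancyModel,
    LinearMortalityModel,
    LogisticMortalityModel,
    ModelParameters,
    MortalityModels,
    SyntheticCohortSpec,
    fit_all_models,
    generate_cohort,
)


def const_models(
    p_elective=0.0,
    p_emergent=0.0,
    p_comp=0.0,
    p_ecomp=0.0,
    p_nonop=0.0,
    life=LifeExpectancyModel(12.0, -3.0),
) -> MortalityModels:
    """MELD-independent probability channels for hand-checkable scenarios."""
    import warnings

    def flat(p):
        return LinearMortalityModel(intercept=p, slope=0.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # emergent < elective is fine here
        return MortalityModels(
            p_elective=flat(p_elective),
            p_emergent=flat(p_emergent),
            p_comp=flat(p_comp),
            p_ecomp=flat(p_ecomp),
            p_nonop=flat(p_nonop),
            life_expectancy=life,
        )


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticCohortSpec(seed=1))


@pytest.fixture(scope="session")
def fitted_models(default_cohort) -> MortalityModels:
    return fit_all_models(default_cohort)


@pytest.fixture(scope="session")
def logistic_recovery_cohort():
    """Large all-nonoperative cohort with known generating coefficients."""
    return generate_cohort(
        SyntheticCohortSpec(
            n_patients=20000,
            operative_fraction=0.0,
            nonop_mortality_coeffs=(-6.0, 0.25),
            median_survival_coeffs=(12.0, -3.0),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def life_recovery_cohort():
    """Cohort for life-expectancy/drift recovery.

    Uses the default (moderate) mortality law so every stratum's target
    median survival is attainable: under 180-day mortality above 50% a
    stratum's median is forced below 180 days regardless of the target.
    """
    return generate_cohort(
        SyntheticCohortSpec(
            n_patients=20000,
            operative_fraction=0.0,
            median_survival_coeffs=(12.0, -3.0),
            annual_meld_drift_mean=1.59,
            seed=11,
        )
    )
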