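import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hernia_markov import (
    LifeExpectancyModel,
    LinearMortalityModel,
    LogisticMortalityModel,
    SyntheticCohortSpec,
    estimate_meld_drift,
    excess_operative_mortality,
    export_mortality_table,
    fit_life_expectancy,
    fit_nonoperative_mortality,
    fit_operative_mortality_line,
    generate_cohort,
    load_mortality_table,
)
from tests.conftest import const_models


# --- logistic nonoperative mortality ---------------------------------------


def test_logistic_recovery(logistic_recovery_cohort):
    model = fit_nonoperative_mortality(logistic_recovery_cohort)
    assert abs(model.slope - 0.25) < 0.02
    assert abs(model.intercept - (-6.0)) < 0.4
    # predictions strictly inside (0, 1)
    for m in (6, 20, 40):
        assert 0.0 < model(m) < 1.0


def test_logistic_single_class_errors():
    frame = pd.DataFrame({"meld_na": [8, 10, 14], "dead_180d": [False] * 3})
    with pytest.raises(ValueError, match="single-class"):
        fit_nonoperative_mortality(frame)


def test_logistic_separation_errors():
    frame = pd.DataFrame({"meld_na": [6, 40], "dead_180d": [False, True]})
    with pytest.raises(ValueError):
        fit_nonoperative_mortality(frame)


def test_logistic_needs_two_meld_values():
    frame = pd.DataFrame({"meld_na": [10, 10], "dead_180d": [False, True]})
    with pytest.raises(ValueError, match="distinct"):
        fit_nonoperative_mortality(frame)


# --- operative lines from stratum means ------------------------------------


def _prediction_frame(meld, values, column="predicted_p_elective"):
    return pd.DataFrame({"meld_na": meld, column: values})


def test_line_exact_recovery():
    meld = np.repeat(np.arange(6, 26), 3)
    frame = _prediction_frame(meld, 0.02 + 0.005 * meld)
    model = fit_operative_mortality_line(frame, "elective")
    assert model.intercept == pytest.approx(0.02, abs=1e-10)
    assert model.slope == pytest.approx(0.005, abs=1e-10)


def test_line_flat_input_zero_slope():
    meld = np.arange(6, 26)
    model = fit_operative_mortality_line(
        _prediction_frame(meld, np.full(meld.size, 0.1)), "elective"
    )
    assert model.slope == pytest.approx(0.0, abs=1e-12)
    assert model.intercept == pytest.approx(0.1, abs=1e-12)


def test_line_uses_stratum_means_not_patient_weights():
    """One stratum with many patients must not outweigh the others."""
    meld = np.array([10] * 100 + [11, 12])
    vals = np.array([0.5] * 100 + [0.1, 0.2])
    many = fit_operative_mortality_line(_prediction_frame(meld, vals), "elective")
    few = fit_operative_mortality_line(
        _prediction_frame([10, 11, 12], [0.5, 0.1, 0.2]), "elective"
    )
    assert many == few


def test_line_invariant_to_patient_order():
    rng = np.random.default_rng(0)
    meld = rng.integers(6, 26, size=200)
    vals = np.clip(0.01 + 0.007 * meld + rng.normal(0, 0.02, 200), 0, 1)
    frame = _prediction_frame(meld, vals)
    shuffled = frame.sample(frac=1.0, random_state=1)
    assert fit_operative_mortality_line(frame, "elective") == (
        fit_operative_mortality_line(shuffled, "elective")
    )


def test_line_noisy_recovery_within_two_se():
    rng = np.random.default_rng(3)
    meld = np.repeat(np.arange(6, 26), 50)
    vals = np.clip(0.01 + 0.007 * meld + rng.normal(0, 0.02, meld.size), 0, 1)
    model = fit_operative_mortality_line(_prediction_frame(meld, vals), "elective")
    # SE of OLS slope over 20 stratum means of 50 noisy points each
    se = (0.02 / np.sqrt(50)) / np.sqrt(np.sum((np.arange(6, 26) - 15.5) ** 2))
    assert abs(model.slope - 0.007) <= 2 * se


def test_line_requires_two_strata():
    with pytest.raises(ValueError, match="strata"):
        fit_operative_mortality_line(
            _prediction_frame([10, 10], [0.1, 0.2]), "elective"
        )


def test_linear_model_clamps_to_unit_interval():
    model = LinearMortalityModel(intercept=-0.5, slope=0.05)
    assert model(6) == 0.0
    assert model(40) == pytest.approx(1.0)
    assert 0.0 < model(20) < 1.0


# --- excess operative mortality ---------------------------------------------


def test_excess_mortality_matches_pointwise_recomputation():
    models = const_models(p_elective=0.2, p_emergent=0.3, p_nonop=0.12)
    assert excess_operative_mortality(models, "elective", 15) == pytest.approx(0.08)
    models2 = const_models(
        p_elective=0.12, p_emergent=0.12, p_nonop=0.12
    )
    for m in range(6, 26):
        assert excess_operative_mortality(models2, "elective", m) == pytest.approx(0.0)

    lin = LinearMortalityModel(0.0, 0.012)
    logi = LogisticMortalityModel(-5.0, 0.12)
    mixed = const_models()
    mixed = type(mixed)(
        p_elective=lin,
        p_emergent=lin,
        p_comp=lin,
        p_ecomp=lin,
        p_nonop=logi,
        life_expectancy=mixed.life_expectancy,
    )
    for m in range(6, 26):
        expected = min(1.0, max(0.0, 0.012 * m)) - expit(-5.0 + 0.12 * m)
        assert excess_operative_mortality(mixed, "elective", m) == pytest.approx(expected)


def test_excess_mortality_rejects_out_of_range_meld():
    with pytest.raises(ValueError):
        excess_operative_mortality(const_models(), "elective", 41)


# --- life expectancy ---------------------------------------------------------


def test_life_expectancy_exact_fit():
    meld = np.repeat(np.arange(8, 20), 5)
    frame = pd.DataFrame(
        {
            "meld_na": meld,
            "survival_years": 12.0 - 3.0 * np.log(meld),
            "event_observed": True,
        }
    )
    model = fit_life_expectancy(frame)
    assert model.a == pytest.approx(12.0, abs=1e-9)
    assert model.b == pytest.approx(-3.0, abs=1e-9)


def test_life_expectancy_floor():
    model = LifeExpectancyModel(a=2.0, b=-3.0, floor=0.25)
    assert model(40) == 0.25  # 2 - 3 ln 40 < 0 -> floored
    healthy = LifeExpectancyModel(a=12.0, b=-3.0, floor=0.25)
    assert healthy(6) == pytest.approx(12.0 - 3.0 * np.log(6.0))


def test_life_expectancy_monotone_decreasing_when_b_negative():
    model = LifeExpectancyModel(a=12.0, b=-3.0)
    grid = np.arange(6.0, 41.0)
    preds = [model(m) for m in grid]
    assert all(a >= b for a, b in zip(preds, preds[1:]))


def test_life_expectancy_recovery_from_synthetic_cohort(life_recovery_cohort):
    import statsmodels.api as sm

    model = fit_life_expectancy(life_recovery_cohort)
    # independent stratum-median OLS with its own standard errors
    frame = life_recovery_cohort
    medians = frame.groupby("meld_na")["survival_years"].median()
    X = sm.add_constant(np.log(medians.index.to_numpy(float)))
    res = sm.OLS(medians.to_numpy(), X).fit()
    se_a, se_b = res.bse
    assert abs(model.a - 12.0) <= 2 * max(se_a, 0.2)
    assert abs(model.b - (-3.0)) <= 2 * max(se_b, 0.1)


def test_life_expectancy_with_censoring_uses_km():
    # independent right-censoring so the Kaplan-Meier median is unbiased
    rng = np.random.default_rng(0)
    meld = np.repeat(np.arange(8, 21), 1000)
    true_median = 12.0 - 3.0 * np.log(meld)
    death = rng.exponential(true_median / np.log(2))
    censor = rng.exponential(4.0 * true_median / np.log(2))
    times = np.minimum(death, censor)
    observed = death <= censor
    frame = pd.DataFrame(
        {
            "meld_na": meld,
            "survival_years": times,
            "event_observed": observed,
        }
    )
    assert (~observed).mean() > 0.1  # censoring actually present
    model = fit_life_expectancy(frame)
    assert model.a == pytest.approx(12.0, abs=2.0)
    assert model.b == pytest.approx(-3.0, abs=0.8)


def test_life_expectancy_needs_estimable_strata():
    frame = pd.DataFrame(
        {
            "meld_na": [10] * 5,
            "survival_years": [1.0] * 5,
            "event_observed": [True] * 5,
        }
    )
    with pytest.raises(ValueError, match="strata"):
        fit_life_expectancy(frame)


# --- drift -------------------------------------------------------------------


@pytest.mark.parametrize(
    "annual,cycle_days,expected",
    [(0.0, 180.0, 0.0), (1.5, 182.625, 0.75), (1.59, 180.0, 1.59 * 180 / 365.25)],
)
def test_estimate_meld_drift(annual, cycle_days, expected):
    frame = pd.DataFrame({"annual_meld_change": [annual] * 10})
    assert estimate_meld_drift(frame, cycle_days) == pytest.approx(expected)


def test_drift_recovery_from_cohort():
    cohort = generate_cohort(
        SyntheticCohortSpec(n_patients=20000, annual_meld_drift_mean=1.59, seed=2)
    )
    drift = estimate_meld_drift(cohort)
    se = 1.0 / np.sqrt(20000) * 180 / 365.25
    assert abs(drift - 1.59 * 180 / 365.25) <= 3 * se


# --- tabulated input ---------------------------------------------------------


def _toy_table(tmp_path, rows):
    path = tmp_path / "table.csv"
    header = "meld,p_elective,p_emergent,p_comp,p_ecomp,p_nonop\n"
    path.write_text(header + "\n".join(rows))
    return path


def test_table_linear_interpolation(tmp_path):
    path = _toy_table(
        tmp_path, [f"{m},{p},{p},{p},{p},{p}" for m, p in [(10, 0.03), (11, 0.05)]]
    )
    models = load_mortality_table(path)
    assert models.p_elective(10.5) == pytest.approx(0.04)
    assert models.p_nonop(10) == pytest.approx(0.03)


def test_table_query_beyond_span_uses_endpoint(tmp_path):
    rows = [f"{m},0.1,0.2,0.1,0.2,0.05" for m in range(6, 41)]
    models = load_mortality_table(_toy_table(tmp_path, rows))
    assert models.p_elective(41) == models.p_elective(40)


def test_table_missing_interior_row_errors(tmp_path):
    rows = [f"{m},0.1,0.2,0.1,0.2,0.05" for m in (10, 11, 13)]
    with pytest.raises(ValueError, match="missing integer"):
        load_mortality_table(_toy_table(tmp_path, rows))


def test_table_out_of_range_probability_errors(tmp_path):
    rows = ["10,0.1,1.2,0.1,0.2,0.05", "11,0.1,0.2,0.1,0.2,0.05"]
    with pytest.raises(ValueError, match="outside"):
        load_mortality_table(_toy_table(tmp_path, rows))


def test_fitted_models_round_trip_through_table(tmp_path, fitted_models):
    path = tmp_path / "export.csv"
    export_mortality_table(fitted_models, path)
    back = load_mortality_table(path, life_expectancy=fitted_models.life_expectancy)
    for m in range(6, 41):
        assert back.p_elective(m) == pytest.approx(fitted_models.p_elective(m))
        assert back.p_nonop(m) == pytest.approx(fitted_models.p_nonop(m))
        assert back.p_ecomp(m) == pytest.approx(fitted_models.p_ecomp(m))
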