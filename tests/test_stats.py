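import numpy as np
import pandas as pd
import pytest

from trunkgait.errors import ModelError
from trunkgait import stats
from trunkgait.synthetic import CohortGenParams, OutcomeModel, gen_cohort

from oracles import normal_equations_ols


def _cohort(n=90, seed=0, noise=0.0, slope=-0.002, intercept=0.9):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 80, n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": age,
            "gender": rng.choice(["F", "M"], n),
            "bmi": rng.normal(24.5, 3.6, n),
        }
    )
    df["y"] = intercept + slope * age + rng.normal(0, noise, n)
    return df


def test_zero_noise_linear_fit_exact():
    df = _cohort(noise=0.0)
    res = stats.fit_age_model(df, "y")
    assert res.slope_age == pytest.approx(-0.002, abs=1e-10)
    assert res.intercept == pytest.approx(0.9, abs=1e-8)
    assert res.quad_age is None
    assert res.rmse == pytest.approx(0.0, abs=1e-8)


def test_fit_matches_normal_equations_oracle():
    df = _cohort(noise=0.05, seed=3)
    res = stats.fit_age_model(df, "y", force_quadratic=False)
    y = df["y"].to_numpy()
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["age"],
            (df["gender"] == "M").astype(float),
            df["bmi"],
        ]
    )
    beta, se, ssr, r2 = normal_equations_ols(y, X)
    assert res.slope_age == pytest.approx(beta[1], abs=1e-8)
    assert res.slope_age_se == pytest.approx(se[1], abs=1e-8)
    assert res.intercept == pytest.approx(beta[0], abs=1e-8)


def test_strong_quadratic_is_retained():
    rng = np.random.default_rng(1)
    df = _cohort(noise=0.0)
    df["y"] = -1.67 + 0.0156 * df["age"] - 0.00016 * df["age"] ** 2 + rng.normal(0, 0.02, len(df))
    res = stats.fit_age_model(df, "y")
    assert res.quad_age is not None
    assert res.quad_age == pytest.approx(-0.00016, abs=2e-5)


def test_rank_deficiency_raises():
    df = _cohort(noise=0.05)
    df["bmi"] = df["age"]  # perfectly collinear covariate
    with pytest.raises(ModelError):
        stats.fit_age_model(df, "y")


def test_ancova_recovers_injected_group_effect():
    """A group effect generating 30% of outcome variance is recovered by
    omega^2 (mean over replicates in [0.25, 0.35])."""
    offsets = np.array([-1.0, -0.6, -0.2, 0.2, 0.6, 1.0])
    offsets = offsets / offsets.std() * np.sqrt(0.3)
    vals = []
    for rep in range(50):
        rng = np.random.default_rng(100 + rep)
        ages = np.concatenate([rng.uniform(d, d + 10, 15) for d in range(20, 80, 10)])
        groups = np.repeat(np.arange(6), 15)
        y = offsets[groups] + rng.normal(0, np.sqrt(0.7), 90)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(90)],
                "age": ages,
                "gender": rng.choice(["F", "M"], 90),
                "bmi": rng.normal(24.5, 3.6, 90),
                "y": y,
            }
        )
        vals.append(stats.ancova_group(df, "y", ci=False).omega2)
    assert 0.25 <= np.mean(vals) <= 0.35


def test_ancova_bootstrap_ci_contains_point_estimate(default_cohort):
    res = stats.ancova_group(default_cohort, "stability_VT", bootstrap_B=200, seed=0)
    lo, hi = res.omega2_ci
    assert lo <= res.omega2 <= hi
    assert res.p_group < 0.05  # strong age trend in the generating model


def test_ancova_rejects_degenerate_groups():
    df = _cohort(n=10)
    with pytest.raises(ModelError):
        stats.ancova_group(df.iloc[:6], "y", ci=False)


def test_posthoc_has_15_bonferroni_capped_contrasts(default_cohort):
    tab = stats.posthoc_pairwise(default_cohort, "stability_VT").contrasts
    assert len(tab) == 15
    np.testing.assert_allclose(
        tab["p_bonferroni"], np.minimum(1.0, 15 * tab["p_raw"]), atol=1e-12
    )
    assert (tab["p_bonferroni"] <= 1.0).all()


def test_delta_r2_nonnegative_and_lrt_consistent(default_cohort):
    for block in ("MET", "MS_average", "MS_diff"):
        res = stats.incremental_block(default_cohort, "step_symmetry_VT", block)
        assert res.delta_r2 >= 0.0
        assert res.significant == (res.lrt_p < 0.05)


def test_collinear_block_gives_zero_delta_r2(default_cohort):
    df = default_cohort.copy()
    df["age_copy"] = df["age"]
    res = stats.incremental_block(df, "step_symmetry_VT", "age_copy")
    assert res.delta_r2 == pytest.approx(0.0, abs=1e-8)


def test_missing_block_column_raises(default_cohort):
    with pytest.raises(ModelError):
        stats.incremental_block(default_cohort, "step_symmetry_VT", "no_such_column")


def test_muscle_models_recover_positive_effect():
    """An injected positive bilateral-strength effect shows up as a
    positive significant coefficient for every muscle group."""
    params = CohortGenParams(strength_effect=0.01, seed=11)
    df = gen_cohort(params)
    tab = stats.muscle_specific_models(
        df, "step_symmetry_VT", ("extensors", "internal_rotators"), measure="ms_average"
    )
    assert (tab["sign"] == "+").all()
    assert tab["significant"].any()


def test_muscle_models_flag_missing_column(default_cohort):
    df = default_cohort.copy()
    df["extensors_ms_average"] = np.nan
    tab = stats.muscle_specific_models(df, "step_symmetry_VT", ("extensors",))
    assert tab.iloc[0]["flag"] == "missing"
    assert not tab.iloc[0]["significant"]


def test_age_decade_labels():
    lab = stats.age_decade(pd.Series([20.0, 29.9, 55.0, 79.9]))
    assert list(lab) == ["20-29", "20-29", "50-59", "70-79"]
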