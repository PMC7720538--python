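"""Study runner: aggregation arithmetic, seeds, calibration of error rates."""

import numpy as np
import pytest

from prepostsim import (
    CalibratedEffects,
    CriterionKind,
    StudyConfig,
    TrueModelSpec,
    count_planned_fits,
    run_cell,
    significance_rate,
    studentized_bias,
    summaries_to_frame,
)
from prepostsim.study import replicate_seed, run_study


class TestSignificanceRate:
    def test_counting(self):
        assert significance_rate([0.01, 0.2, 0.04, 0.9], 0.05) == 0.5
        assert significance_rate([1.0, 1.0, 1.0], 0.05) == 0.0

    def test_strict_inequality(self):
        assert significance_rate([0.05, 0.049999], 0.05) == 0.5

    def test_uniform_null(self):
        rng = np.random.default_rng(1)
        assert significance_rate(rng.uniform(size=1000), 0.05) == pytest.approx(
            0.05, abs=0.02
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            significance_rate([])
        with pytest.raises(ValueError):
            significance_rate([1.5])


class TestStudentizedBias:
    def test_zero_bias(self):
        est = np.array([1.0, 2.0, 3.0])
        assert studentized_bias(est, est, 100) == 0.0

    def test_constant_offset_formula(self):
        rng = np.random.default_rng(2)
        tru = rng.normal(size=500)
        obs = tru + 0.3
        # paired offsets shift mean bias but SD comes from the observed estimates
        expected = 0.3 / (np.std(obs, ddof=1) * np.sqrt(200))
        assert studentized_bias(obs, tru, 200) == pytest.approx(expected)

    def test_sqrt_n_scaling(self):
        rng = np.random.default_rng(3)
        tru = rng.normal(size=100)
        obs = tru + rng.normal(0.2, 0.1, size=100)
        assert studentized_bias(obs, tru, 100) == pytest.approx(
            np.sqrt(2) * studentized_bias(obs, tru, 200)
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            studentized_bias([1.0], [1.0], 10)
        with pytest.raises(ValueError):
            studentized_bias([1.0, 1.0], [0.0, 0.0], 10)


class TestPlannedFitCount:
    def test_default_grid_matches_study_scale(self):
        assert count_planned_fits(StudyConfig()) == 1_280_000

    def test_minimal_and_reduced_configs(self):
        one = StudyConfig(
            n_grid=(50,), reliability_grid=(0.8,), replications=1,
            model_ids=(1,), criteria=(CriterionKind.POST_TEST,),
        )
        assert count_planned_fits(one) == 2
        reduced = StudyConfig(n_grid=(100,), reliability_grid=(0.8,), replications=1000)
        assert count_planned_fits(reduced) == 40_000


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replications": 0},
            {"n_grid": (201,)},
            {"n_grid": ()},
            {"reliability_grid": (1.2,)},
            {"alpha": 0.0},
            {"model_ids": (0, 1)},
        ],
    )
    def test_rejects(self, kwargs):
        with pytest.raises(ValueError):
            StudyConfig(**kwargs)


def test_replicate_seed_stability():
    a = replicate_seed(7, 100, 0.8, 3)
    b = replicate_seed(7, 100, 0.8, 3)
    assert a.entropy == b.entropy
    assert replicate_seed(7, 100, 0.8, 4).entropy != a.entropy
    assert replicate_seed(7, 100, 0.7, 3).entropy != a.entropy


@pytest.fixture(scope="module")
def small_cell(effects, spec):
    config = StudyConfig(
        n_grid=(100,), reliability_grid=(0.8,), replications=150, master_seed=99,
        model_ids=(2, 4), criteria=(CriterionKind.POST_TEST, CriterionKind.ABSOLUTE_CHANGE),
    )
    cells, biases = run_cell(config, effects, spec, 100, 0.8)
    return config, cells, biases


def test_run_cell_determinism(effects, spec, small_cell):
    config, cells, biases = small_cell
    cells2, biases2 = run_cell(config, effects, spec, 100, 0.8)
    f1 = summaries_to_frame(cells, biases)
    f2 = summaries_to_frame(cells2, biases2)
    assert f1.equals(f2)


def test_run_cell_shape_and_aggregates(small_cell):
    config, cells, biases = small_cell
    df = summaries_to_frame(cells, biases)
    # 2 models x 2 criteria x 2 sources, term rows: model 2 has 4, model 4 has 7
    assert len(df) == 2 * 2 * (4 + 7)
    assert (df["n_ok"] == config.replications).all()
    assert (df["SE"] >= 0).all()
    assert df["P"].between(0, 1).all()
    # P * replications must be an integer count of significant replicates
    counts = df["P"] * config.replications
    np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
    # studentized bias defined (finite) on observed rows, absent on true rows
    obs = df[df.data_source == "observed"]
    assert np.isfinite(obs["studentized_bias"]).all()
    assert df[df.data_source == "true"]["studentized_bias"].isna().all()


def test_true_fits_recover_interaction_coefficient(effects, spec, small_cell):
    # noise-free Model-4 change-score fits estimate the true p1 slope difference
    _, cells, _ = small_cell
    true_m4 = next(
        c
        for c in cells
        if c.model_id == 4
        and c.criterion is CriterionKind.ABSOLUTE_CHANGE
        and c.data_source == "true"
    )
    assert true_m4.M["p1:group"] == pytest.approx(effects.beta_true_p1, abs=0.02)
    assert true_m4.M["p1"] == pytest.approx(0.0, abs=0.02)


def test_alpha_calibration_under_pure_null(spec):
    """With no true effects and perfect reliability, every P estimates alpha."""
    null_effects = CalibratedEffects(
        mu_delta_exp=0.0, mu_delta_ctl=0.0, var_delta_exp=69.0,
        r_true_p1=0.0, beta_true_p1=0.0,
    )
    config = StudyConfig(
        n_grid=(100,), reliability_grid=(1.0,), replications=400, master_seed=17,
        model_ids=(3,),
        criteria=(CriterionKind.POST_TEST, CriterionKind.ABSOLUTE_CHANGE),
    )
    cells, _ = run_cell(config, null_effects, spec, 100, 1.0)
    for cell in cells:
        for term in ("p1", "p2"):
            assert 0.02 <= cell.P[term] <= 0.09, (cell.criterion, term, cell.P[term])


def test_se_shrinks_like_sqrt_n(effects, spec):
    config = lambda n: StudyConfig(  # noqa: E731
        n_grid=(n,), reliability_grid=(0.8,), replications=250, master_seed=55,
        model_ids=(2,), criteria=(CriterionKind.ABSOLUTE_CHANGE,),
    )
    ses = {}
    for n in (100, 400):
        cells, _ = run_cell(config(n), effects, spec, n, 0.8)
        obs = next(c for c in cells if c.data_source == "observed")
        ses[n] = obs.SE["p1"]
    assert ses[100] / ses[400] == pytest.approx(2.0, rel=0.2)


def test_run_study_over_tiny_grid(effects, spec):
    config = StudyConfig(
        n_grid=(50, 100), reliability_grid=(0.7,), replications=30, master_seed=4,
        model_ids=(2,), criteria=(CriterionKind.ABSOLUTE_CHANGE,),
    )
    df = run_study(config, spec)
    assert sorted(df["n"].unique()) == [50, 100]
    assert set(df["data_source"]) == {"observed", "true"}
    df2 = run_study(config, spec)
    assert df.equals(df2)
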