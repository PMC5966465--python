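"""Group-level bootstrap regression, collinearity, transforms, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdpe.regression import (
    MODEL_SPECS,
    PERegression,
    bonferroni,
    bootstrap_inference,
    collinearity,
    enter_regression,
    rank_transform_if_nonnormal,
    run_model_suite,
)


def make_X(n, p, rng, names=None):
    X = rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=names or [f"x{j}" for j in range(p)])


# -- point estimates ---------------------------------------------------------

def test_exact_linear_fit(rng):
    X = make_X(40, 3, rng)
    y = 1.0 + 2.0 * X["x0"] - 0.5 * X["x2"]
    res = enter_regression(y.to_numpy(), X)
    assert res.r_squared == pytest.approx(1.0)


def test_single_predictor_beta_is_pearson_r(rng):
    X = make_X(60, 1, rng)
    y = 0.8 * X["x0"].to_numpy() + rng.normal(size=60)
    res = enter_regression(y, X)
    r = stats.pearsonr(y, X["x0"])[0]
    assert res.params.loc["x0", "beta_std"] == pytest.approx(r, abs=1e-12)


def test_standardized_effect_recovery(rng):
    """Generating model with standardized effects (-0.5, +0.4, -0.45) and
    unit total variance: fitted standardized betas recover them at n=500."""
    effects = np.array([-0.5, 0.4, -0.45])
    noise_sd = np.sqrt(1.0 - (effects**2).sum())
    n = 500
    X = make_X(n, 3, rng)
    Z = (X - X.mean()) / X.std(ddof=1)
    y = Z.to_numpy() @ effects + rng.normal(0, noise_sd, n)
    res = enter_regression(y, X)
    assert np.allclose(res.params["beta_std"], effects, atol=0.05)


def test_beta_affine_invariance(rng):
    X = make_X(50, 2, rng)
    y = X["x0"].to_numpy() - X["x1"].to_numpy() + rng.normal(size=50)
    b1 = enter_regression(y, X).params["beta_std"]
    X2 = X.copy()
    X2["x0"] = 100.0 * X2["x0"] - 7.0
    b2 = enter_regression(3.0 * y + 11.0, X2).params["beta_std"]
    assert np.allclose(b1, b2, atol=1e-10)


def test_rank_deficiency_names_columns(rng):
    X = make_X(30, 2, rng)
    X["dup"] = X["x1"]
    y = rng.normal(size=30)
    with pytest.raises(np.linalg.LinAlgError, match="dup"):
        PERegression(y, X).fit(bootstrap=None)


def test_n_must_exceed_p_plus_one(rng):
    X = make_X(4, 3, rng)
    with pytest.raises(ValueError, match="n > p"):
        PERegression(rng.normal(size=4), X)


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_zero_variance_y_errors(rng):
    X = make_X(20, 2, rng)
    with pytest.raises(ValueError, match="zero variance"):
        bootstrap_inference(np.ones(20), X, B=200, seed=1)


def test_bootstrap_p_floor(rng):
    """Very strong effect: p hits its 2/(B+1) floor, never zero."""
    X = make_X(60, 1, rng)
    y = X["x0"].to_numpy() + 0.01 * rng.normal(size=60)
    out = bootstrap_inference(y, X, B=999, seed=2)
    assert out.loc["x0", "p_boot"] == pytest.approx(2 / 1000)


def test_bootstrap_ci_collapses_on_exact_single_predictor_fit(rng):
    """Noiseless one-predictor fit: every resample's standardized beta is
    the same +/-1 correlation, so the percentile CI has zero width."""
    X = make_X(40, 1, rng)
    y = 2.0 * X["x0"].to_numpy() + 3.0
    out = bootstrap_inference(y, X, B=300, seed=3)
    assert out.loc["x0", "ci_high"] - out.loc["x0", "ci_low"] == pytest.approx(0.0)
    assert out.loc["x0", "beta_std"] == pytest.approx(1.0)


def test_bootstrap_power_strong_effect(rng):
    """beta=0.8 at n=33: significant at 0.05 in well over 90% of datasets."""
    hits = 0
    reps = 60
    for _ in range(reps):
        X = make_X(33, 1, rng)
        z = (X["x0"] - X["x0"].mean()) / X["x0"].std(ddof=1)
        y = 0.8 * z.to_numpy() + np.sqrt(1 - 0.64) * rng.normal(size=33)
        out = bootstrap_inference(y, X, B=500, seed=rng)
        hits += out.loc["x0", "p_boot"] < 0.05
    assert hits / reps > 0.9


def test_bootstrap_seed_reproducible(rng):
    X = make_X(33, 2, rng)
    y = rng.normal(size=33)
    a = bootstrap_inference(y, X, B=300, seed=7)
    b = bootstrap_inference(y, X, B=300, seed=7)
    pd.testing.assert_frame_equal(a, b)


# -- collinearity ------------------------------------------------------------

def _orthonormal_centered(n, k, rng):
    """Zero-mean, mutually orthonormal columns (Gram-Schmidt after demeaning)."""
    A = rng.normal(size=(n, k))
    A -= A.mean(axis=0)
    q, _ = np.linalg.qr(A)
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    return q


def test_orthogonal_predictors_unit_vif():
    q = _orthonormal_centered(30, 3, np.random.default_rng(0))
    X = pd.DataFrame(q, columns=list("abc"))
    tab = collinearity(X)
    assert np.allclose(tab["vif"], 1.0, atol=1e-10)
    assert np.allclose(tab["tolerance"], 1.0, atol=1e-10)
    assert not tab["flagged"].any()


def test_duplicated_predictor_infinite_vif(rng):
    X = make_X(30, 1, rng)
    X["dup"] = X["x0"]
    tab = collinearity(X)
    assert np.isinf(tab["vif"]).all()
    assert tab["flagged"].all()


@pytest.mark.parametrize("r", [np.sqrt(0.5), np.sqrt(0.79), np.sqrt(0.81), 0.95])
def test_two_predictor_vif_matches_analytic(r, rng):
    """Pairs built with exact sample correlation r: VIF = 1/(1-r^2) and the
    flag fires iff that analytic value exceeds 5."""
    q = _orthonormal_centered(50, 2, rng)
    x1 = q[:, 0]
    x2 = r * q[:, 0] + np.sqrt(1 - r**2) * q[:, 1]
    tab = collinearity(pd.DataFrame({"x1": x1, "x2": x2}))
    expected = 1.0 / (1.0 - r**2)
    assert np.allclose(tab["vif"], expected, rtol=1e-8)
    assert tab["flagged"].all() == (expected > 5.0)


def test_constant_column_flagged():
    X = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
    tab = collinearity(X)
    assert np.isinf(tab.loc["c", "vif"]) and tab.loc["c", "flagged"]


# -- rank transform / bonferroni --------------------------------------------

def test_rank_transform_idempotent(rng):
    heavy = rng.normal(size=100) ** 3
    ranked, flag = rank_transform_if_nonnormal(heavy)
    assert flag
    again, _ = rank_transform_if_nonnormal(ranked)
    assert np.array_equal(stats.rankdata(ranked), stats.rankdata(again))


def test_rank_transform_triggers_on_heavy_tails(rng):
    assert rank_transform_if_nonnormal(rng.normal(size=200) ** 3)[1]


def test_rank_transform_leaves_ideal_normal_scores():
    scores = stats.norm.ppf((np.arange(1, 201) - 0.5) / 200)
    out, flag = rank_transform_if_nonnormal(scores)
    assert not flag
    assert np.array_equal(out, scores)


@pytest.mark.parametrize(
    "p,m,expected", [(0.001, 8, 0.008), (0.2, 8, 1.0), (0.05 / 8, 8, 0.05)]
)
def test_bonferroni_adjustment(p, m, expected):
    adj, _ = bonferroni([p], m)
    assert adj[0] == pytest.approx(expected)


def test_bonferroni_family_too_small():
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)


# -- model suite -------------------------------------------------------------

@pytest.fixture(scope="module")
def suite_dataset():
    """Cohort with D2-genotype-only effects in the putamen.

    BMI is left null because every predictor grouping shares it: a BMI
    effect would make the D1/OTHER model F-tests significant as well,
    defeating the specificity check.
    """
    from tdpe.simulate import CohortConfig, generate_cohort, simulate_roi_estimates

    cfg = CohortConfig(
        n_subjects=120, seed=21, noise_sd=0.2,
        effects={"code_rs1799732": 0.4, "code_rs1800497": -0.45},
    )
    obs, truth = generate_cohort(cfg)
    return simulate_roi_estimates(obs, truth, sigma=0.5, seed=22)


def test_suite_shape_and_specificity(suite_dataset):
    """D2 effects planted in the putamen: the D2 model is significant there
    after correction; D1/OTHER stay non-significant at family level."""
    table = run_model_suite(suite_dataset, B=500, seed=30)
    assert set(table["spec"]) == {"D2", "D1", "OTHER"}
    assert len(table[table.spec == "D2"]) == 8 * 3  # 8 ROIs x 3 predictors
    d2_put = table[(table.spec == "D2") & (table.roi == "putamen_right")]
    assert (d2_put["model_p_bonf"] < 0.05).all()
    signs = d2_put.set_index("predictor")["beta_std"]
    assert signs["code_rs1799732"] > 0 and signs["code_rs1800497"] < 0
    for spec in ("D1", "OTHER"):
        sub = table[(table.spec == spec) & (table.roi == "putamen_right")]
        assert (sub["model_p_bonf"] > 0.05).all()


def test_suite_complete_case_bookkeeping(suite_dataset):
    data = suite_dataset.copy()
    data.loc[data.index[0], "code_rs686"] = np.nan
    table = run_model_suite(data, specs=["D2", "D1"], rois=["putamen_left"],
                            B=200, seed=1)
    n_d2 = table[table.spec == "D2"]["n"].iloc[0]
    n_d1 = table[table.spec == "D1"]["n"].iloc[0]
    assert n_d2 == len(data)
    assert n_d1 == len(data) - 1
    assert table[table.spec == "D1"]["n_dropped"].iloc[0] == 1
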