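"""ZICMP mixed model: CMP primitives, likelihood oracles, fitting, prediction."""

import math

import numpy as np
import pytest
from scipy import special

from paintraj import synthetic
from paintraj.zicmp import (
    CmpParams,
    ZicmpSpec,
    cmp_log_pmf,
    cmp_mean,
    cmp_pmf_vector,
    cmp_var,
    fit_zicmp,
    predict_decomposition,
    predict_subject_curves,
    zicmp_loglik,
)
from tests.conftest import make_series

PARAM_GRID = [(0.5, 0.3), (0.9, 0.0), (1.5, 1.0), (3.0, 0.5), (5.0, 2.0),
              (8.0, 1.3), (12.0, 3.0), (0.2, 0.8)]


def test_cmp_pmf_normalizes():
    for lam, nu in PARAM_GRID:
        pmf = cmp_pmf_vector(CmpParams(lam, nu), 2000)
        assert abs(pmf.sum() - 1.0) < 1e-10, (lam, nu)
        assert np.all(pmf >= 0)


def test_cmp_poisson_closed_form():
    from scipy import stats

    for lam in (0.5, 2.0, 7.5):
        y = np.arange(0, 40)
        ours = cmp_log_pmf(y, CmpParams(lam, 1.0))
        assert np.allclose(ours, stats.poisson.logpmf(y, lam), atol=1e-10)
        assert cmp_mean(CmpParams(lam, 1.0)) == pytest.approx(lam, abs=1e-9)
        assert cmp_var(CmpParams(lam, 1.0)) == pytest.approx(lam, abs=1e-8)


def test_cmp_geometric_closed_form():
    # nu = 0, lam < 1: pmf(y) = (1 - lam) lam^y, mean lam / (1 - lam)
    lam = 0.6
    y = np.arange(0, 60)
    expected = np.log(1 - lam) + y * np.log(lam)
    assert np.allclose(cmp_log_pmf(y, CmpParams(lam, 0.0)), expected, atol=1e-10)
    assert cmp_mean(CmpParams(lam, 0.0)) == pytest.approx(lam / (1 - lam), abs=1e-9)


def test_cmp_dispersion_ordering():
    # nu > 1 -> underdispersed (var < mean); nu < 1 -> overdispersed
    lam = 4.0
    assert cmp_var(CmpParams(lam, 2.5)) < cmp_mean(CmpParams(lam, 2.5))
    assert cmp_var(CmpParams(lam, 0.5)) > cmp_mean(CmpParams(lam, 0.5))


def test_cmp_params_validation():
    with pytest.raises(ValueError):
        CmpParams(-1.0, 1.0)
    with pytest.raises(ValueError):
        CmpParams(2.0, -0.1)
    with pytest.raises(ValueError):
        CmpParams(1.5, 0.0)  # divergent series at nu = 0
    with pytest.raises(ValueError):
        cmp_log_pmf([1.5], CmpParams(1.0, 1.0))


def _tiny_cohort(n=5, seed=3):
    cfg = synthetic.well_separated_scenario(n_patients=n, seed=seed)
    series, _, _ = synthetic.generate_cohort(cfg)
    return series


PARAMS = {"beta": [1.5, -0.5, 0.1], "gamma": [-1.0, 0.5, 0.2],
          "nu": 1.3, "sigma_b": 0.25}


def test_laplace_close_to_agq20():
    series = _tiny_cohort()
    lap = zicmp_loglik(PARAMS, series, method="laplace")
    agq = zicmp_loglik(PARAMS, series, method="agq", agq_nodes=20)
    assert abs(lap - agq) / abs(agq) < 1e-4


def test_agq_node_count_converged():
    series = _tiny_cohort()
    a20 = zicmp_loglik(PARAMS, series, method="agq", agq_nodes=20)
    a40 = zicmp_loglik(PARAMS, series, method="agq", agq_nodes=40)
    assert abs(a20 - a40) / abs(a40) < 1e-8


def test_sigma_zero_loglik_manual_oracle():
    """With sigma_b = 0 the marginal likelihood is an independent ZICMP
    product; compare against a direct per-observation summation."""
    series = [make_series("A", (1.0, 10.0, 40.0, 80.0), (0, 3, 5, 2)),
              make_series("B", (2.0, 30.0, 60.0, 90.0), (4, 0, 0, 1))]
    spec = ZicmpSpec()
    params = {"beta": [1.2, -0.4, 0.05], "gamma": [-0.8, 0.3, 0.1],
              "nu": 1.1, "sigma_b": 0.0}
    manual = 0.0
    for s in series:
        for t, y in zip(s.times, s.scores):
            sscale = t / spec.window_h
            log_lam = params["beta"][0] + params["beta"][1] * sscale \
                + params["beta"][2] * sscale ** 2
            zi = params["gamma"][0] + params["gamma"][1] * sscale \
                + params["gamma"][2] * sscale ** 2
            pi = special.expit(zi)
            lp_count = float(cmp_log_pmf(int(y), CmpParams(math.exp(log_lam),
                                                           params["nu"])))
            if y == 0:
                manual += math.log(pi + (1 - pi) * math.exp(lp_count))
            else:
                manual += math.log(1 - pi) + lp_count
    ours = zicmp_loglik(params, series, spec)
    assert ours == pytest.approx(manual, rel=1e-12)


def test_reduces_to_poisson_glm():
    import statsmodels.api as sm

    series = _tiny_cohort(n=12, seed=7)
    spec = ZicmpSpec()
    fit = fit_zicmp(series, spec, fix_nu=1.0, fix_sigma_b=0.0,
                    zero_inflation=False, compute_se=False)
    y = np.concatenate([s.scores for s in series])
    t = np.concatenate([s.times for s in series])
    glm = sm.GLM(y, spec.count_design(t), family=sm.families.Poisson()).fit()
    assert abs(fit.loglik - glm.llf) / abs(glm.llf) < 1e-6
    assert np.allclose(fit.beta, glm.params, atol=1e-4)


def test_fit_recovers_on_moderate_cohort():
    cfg = synthetic.well_separated_scenario(n_patients=60, seed=4)
    series, _, labels = synthetic.generate_cohort(cfg)
    members = [s for s in series if labels[s.patient_id] == 1]
    fit = fit_zicmp(members, starts="warm")
    assert fit.converged
    assert 0.0 < fit.nu < 20.0 and fit.sigma_b >= 0.0
    assert fit.se is not None and np.all(np.isfinite(fit.se["beta"]))
    tbl = fit.coefficient_table()
    assert set(tbl["submodel"]) == {"count", "zero_inflation", "dispersion",
                                    "random_intercept"}
    assert len(tbl) == len(fit.beta) + len(fit.gamma) + 2


@pytest.fixture(scope="module")
def small_fit():
    series = _tiny_cohort(n=25, seed=9)
    return fit_zicmp(series, starts="warm", compute_se=False)


def test_decomposition_identity(small_fit):
    grid = np.linspace(0.0, 96.0, 97)
    for mode in ("population", "marginal"):
        df = predict_decomposition(small_fit, grid, mode=mode, force=True)
        ok = df["p_pain"] > 0
        assert np.allclose(df.loc[ok, "mean_pain"],
                           df.loc[ok, "p_pain"] * df.loc[ok, "cond_intensity"],
                           atol=1e-10)
        assert np.all((df["pi"] >= 0) & (df["pi"] <= 1))
        assert np.all((df["p_pain"] >= 0) & (df["p_pain"] <= 1))
    with pytest.raises(ValueError, match="unknown mode"):
        predict_decomposition(small_fit, grid, mode="nope", force=True)


def test_unconverged_fit_refuses_prediction(small_fit):
    import dataclasses

    bad = dataclasses.replace(small_fit, converged=False)
    with pytest.raises(RuntimeError, match="unconverged"):
        predict_decomposition(bad)
    # force=True overrides
    predict_decomposition(bad, np.array([0.0, 48.0, 96.0]), force=True)


def test_subject_curves_shapes(small_fit):
    grid, p, m = predict_subject_curves(small_fit, np.linspace(0, 96, 25))
    assert p.shape == (small_fit.n_patients, 25) == m.shape
    assert np.all((p >= 0) & (p <= 1)) and np.all(m >= 0)
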