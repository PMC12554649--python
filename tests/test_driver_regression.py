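import numpy as np
import pandas as pd
import pytest

from ruralcoord.driver_regression import (
    bootstrap_inference,
    pinball_loss,
    quantile_fit,
    quantile_table,
    transform_drivers,
)


def grid_oracle_intercept(y, tau, grid):
    losses = [pinball_loss(y - b, tau) for b in grid]
    return grid[int(np.argmin(losses))]


def test_median_of_three_is_two():
    fit = quantile_fit(np.empty((3, 0)), [1.0, 2.0, 3.0], 0.5)
    assert fit.beta[0] == pytest.approx(2.0, abs=1e-9)


def test_intercept_only_matches_grid_oracle():
    y = np.array([0.0, 10.0])
    grid = np.linspace(-1, 11, 2401)
    b_ref = grid_oracle_intercept(y, 0.9, grid)
    fit = quantile_fit(np.empty((2, 0)), y, 0.9)
    assert pinball_loss(y - fit.beta[0], 0.9) <= pinball_loss(y - b_ref, 0.9) + 1e-10


@pytest.mark.parametrize("tau", [0.1, 0.25, 0.5, 0.75, 0.9])
def test_noiseless_linear_data_recovered_exactly(tau):
    x = np.linspace(0, 1, 15)
    y = 1.0 + 2.0 * x
    fit = quantile_fit(x[:, None], y, tau)
    assert np.allclose(fit.beta, [1.0, 2.0], atol=1e-8)
    assert fit.loss == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed,tau", [(0, 0.25), (1, 0.5), (2, 0.8)])
def test_pinball_loss_matches_independent_solver(seed, tau):
    """The LP's attained loss matches statsmodels' quantile fit."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(seed)
    n = 60
    X = rng.normal(size=(n, 3))
    y = 0.5 + X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=n)
    fit = quantile_fit(X, y, tau)
    Xc = sm.add_constant(X)
    ref = sm.QuantReg(y, Xc).fit(q=tau, p_tol=1e-10)
    loss_ref = pinball_loss(y - Xc @ ref.params, tau)
    assert fit.loss <= loss_ref + 1e-8
    assert abs(fit.loss - loss_ref) < 1e-6 * max(1.0, loss_ref)


def test_subgradient_optimality_condition():
    rng = np.random.default_rng(7)
    n, p = 80, 3
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    for tau in (0.2, 0.5, 0.7):
        fit = quantile_fit(X, y, tau)
        neg = np.mean(fit.residuals < -1e-9)
        nonpos = np.mean(fit.residuals <= 1e-9)
        k = p + 1
        assert neg <= tau + k / n
        assert nonpos >= tau - k / n
        assert fit.loss <= pinball_loss(y, tau)  # beats the zero fit


def test_equivariance_to_scaling_and_shift():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 2))
    y = rng.normal(size=40)
    base = quantile_fit(X, y, 0.3)
    scaled = quantile_fit(X, 3.0 * y, 0.3)
    assert np.allclose(scaled.beta, 3.0 * base.beta, atol=1e-7)
    shifted = quantile_fit(X, y + 5.0, 0.3)
    assert shifted.beta[0] == pytest.approx(base.beta[0] + 5.0, abs=1e-7)
    assert np.allclose(shifted.beta[1:], base.beta[1:], atol=1e-7)


def test_rank_deficient_design_names_columns():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    with pytest.raises(ValueError, match="collinear"):
        quantile_fit(X, [1.0, 2, 3, 4], 0.5)


def test_bootstrap_reproducible_and_detects_strong_signal():
    rng = np.random.default_rng(5)
    n = 120
    x = rng.normal(size=n)
    y = 2.0 * x + 0.2 * rng.normal(size=n)
    a = bootstrap_inference(x[:, None], y, 0.5, n_boot=200, seed=9)
    b = bootstrap_inference(x[:, None], y, 0.5, n_boot=200, seed=9)
    assert np.allclose(a.t_stats, b.t_stats)
    assert abs(a.t_stats[1]) > 1.96  # slope effect >> noise
    assert a.ci[1, 0] < 2.0 < a.ci[1, 1]


def test_bootstrap_null_coverage():
    """Under a zero-signal design the slope t-statistic rarely exceeds 1.96."""
    rng = np.random.default_rng(0)
    n = 150
    exceed = 0
    reps = 40
    for r in range(reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fit = bootstrap_inference(x[:, None], y, 0.5, n_boot=120, seed=r)
        exceed += abs(fit.t_stats[1]) > 1.96
    assert exceed / reps <= 0.2  # nominal 5%, generous Monte-Carlo slack


def test_transform_log_z_standardises():
    df = pd.DataFrame(
        {
            "LED": [1e4, 2e4, 4e4],
            "HNL": [100.0, 200, 400],
            "DIN": [1.0, 2, 3],
            "GOV": [1e6, 2e6, 4e6],
            "HHC": [1.0, 2, 3],
            "URB": [40.0, 50, 60],
        }
    )
    X = transform_drivers(df)
    assert np.allclose(X.mean(), 0, atol=1e-12)
    assert np.allclose(X.std(ddof=1), 1, atol=1e-12)
    # log makes the geometric progression exactly linear
    assert np.allclose(np.diff(X["LED"]), np.diff(X["LED"])[0])


def test_quantile_table_structure(default_run):
    gen = default_run["gen"]
    D = default_run["ccd"].set_index(["unit", "year"])["D"]
    qt = quantile_table(gen.panel, D, taus=(0.5,), n_boot=150, seed=0)
    assert qt.attrs["n_obs"] == 232
    assert list(qt.index) == ["LED", "HNL", "DIN", "GOV", "HHC", "URB", "const"]
    assert qt.columns.get_level_values("tau").unique().tolist() == [0.5]
    truth = gen.truth.driver_betas
    for drv, beta in truth.items():
        assert np.sign(qt.loc[drv, (0.5, "beta")]) == np.sign(beta)
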