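"""The inference chain against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from allelemeth.bootstrap import bca_interval, case_resample
from allelemeth.stats import (BootstrapLogit, BootstrapOLS, adjust_pvalues,
                              anova_eta, conditional_spearman,
                              contingency_chisq, hwe_test, kruskal_dunn,
                              ld_stats, normality_gate, stepwise_select)


# ---------------------------------------------------------------------------
# point estimation vs independent solvers
# ---------------------------------------------------------------------------

def normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


def newton_logistic(X, y, iters=100):
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-X @ beta))
        W = p * (1 - p)
        step = np.linalg.solve((X.T * W) @ X, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def test_ols_exact_line():
    x = np.arange(10.0)
    res = BootstrapOLS(2 * x + 1, pd.DataFrame({"x": x}), B=20, seed=0).fit()
    assert res.params["const"] == pytest.approx(1.0)
    assert res.params["x"] == pytest.approx(2.0)


def test_ols_matches_normal_equations_on_random_data():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n, k = 40, 3
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        res = BootstrapOLS(y, pd.DataFrame(X), B=5, seed=0,
                           accelerated=False).fit(compute_p=False)
        oracle = normal_equations(np.column_stack([np.ones(n), X]), y)
        assert np.allclose(res.params.to_numpy(), oracle, atol=1e-8)


def test_logistic_matches_newton_oracle():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n = 120
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        res = BootstrapLogit(y, pd.DataFrame({"x": x}), B=5, seed=0,
                             accelerated=False).fit(compute_p=False)
        oracle = newton_logistic(np.column_stack([np.ones(n), x]), y)
        assert np.allclose(res.params.to_numpy(), oracle, atol=1e-6)


def test_logistic_null_slope_near_zero():
    rng = np.random.default_rng(9)
    n = 400
    x = rng.normal(size=n)
    y = (rng.random(n) < 0.5).astype(float)
    res = BootstrapLogit(y, pd.DataFrame({"x": x}), B=5, seed=0,
                         accelerated=False).fit(compute_p=False)
    assert abs(res.params["x"]) < 0.3


def test_aliased_column_dropped_with_warning():
    rng = np.random.default_rng(10)
    x = rng.normal(size=30)
    X = pd.DataFrame({"x": x, "x2": 2 * x})
    with pytest.warns(UserWarning, match="aliased"):
        res = BootstrapOLS(x, X, B=5, seed=0, accelerated=False).fit(
            compute_p=False)
    assert "x2" in res.dropped


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def test_bca_close_to_percentile_for_symmetric_mean():
    rng = np.random.default_rng(11)
    data = rng.normal(size=300)
    ci = bca_interval(data, np.mean, B=2000, seed=5)
    theta_b = case_resample(data, np.mean, 2000, np.random.default_rng(5))
    lo, hi = np.quantile(theta_b, [0.025, 0.975])
    assert ci.ci_low == pytest.approx(lo, abs=0.02)
    assert ci.ci_high == pytest.approx(hi, abs=0.02)
    assert abs(ci.z0) < 0.1 and abs(ci.accel) < 0.05


def test_bca_location_equivariance_for_mean():
    rng = np.random.default_rng(12)
    data = rng.exponential(size=80)
    a = bca_interval(data, np.mean, B=500, seed=3)
    b = bca_interval(data + 10.0, np.mean, B=500, seed=3)
    assert b.ci_low == pytest.approx(a.ci_low + 10.0, abs=1e-9)
    assert b.ci_high == pytest.approx(a.ci_high + 10.0, abs=1e-9)


def test_degenerate_bootstrap_falls_back_to_percentile():
    data = np.ones(20)
    with pytest.warns(UserWarning, match="degenerate"):
        ci = bca_interval(data, np.mean, B=50, seed=0)
    assert ci.method == "percentile" and ci.ci_low == ci.ci_high == 1.0


def test_bootstrap_needs_ten_cases():
    with pytest.raises(ValueError, match="10"):
        bca_interval(np.arange(5.0), np.mean, B=50, seed=0)


def test_bca_endpoints_match_r_boot_package(tmp_path):
    """Independent cross-check: BCa endpoints agree with R's boot package
    (different resample streams, so agreement is within bootstrap noise)."""
    import subprocess

    rng = np.random.default_rng(42)
    n = 60
    x = rng.normal(size=n)
    y = 0.3 * x + rng.exponential(size=n) - 1
    data = np.column_stack([x, y])
    tsv = tmp_path / "d.tsv"
    np.savetxt(tsv, data, delimiter="\t")

    def slope(d):
        xc = d[:, 0] - d[:, 0].mean()
        return float(xc @ d[:, 1] / (xc @ xc))

    ci = bca_interval(data, slope, B=4000, seed=1, compute_p=False)
    script = f"""
    library(boot)
    d <- as.matrix(read.table('{tsv}'))
    slope <- function(data, idx) {{ dd <- data[idx,]
      xc <- dd[,1]-mean(dd[,1]); sum(xc*dd[,2])/sum(xc*xc) }}
    set.seed(1)
    ci <- boot.ci(boot(d, slope, R=4000), type='bca')
    cat(ci$bca[4], ci$bca[5], sep='\\n')
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    r_lo, r_hi = (float(v) for v in out.stdout.strip().split())
    assert ci.ci_low == pytest.approx(r_lo, abs=0.03)
    assert ci.ci_high == pytest.approx(r_hi, abs=0.03)


def test_bca_p_value_consistent_with_interval():
    """p < 0.05 iff the 95% interval excludes zero (by construction of the
    inversion, up to grid resolution)."""
    rng = np.random.default_rng(13)
    for shift in (0.0, 1.0):
        data = rng.normal(loc=shift, size=60)
        ci = bca_interval(data, np.mean, B=999, seed=1)
        excludes = ci.ci_low > 0 or ci.ci_high < 0
        assert (ci.p_value < 0.05) == excludes


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def test_kruskal_two_groups_equals_mann_whitney():
    rng = np.random.default_rng(14)
    x = np.concatenate([rng.normal(size=25), rng.normal(0.8, 1, size=30)])
    g = np.array(["a"] * 25 + ["b"] * 30)
    kw, _ = kruskal_dunn(x, g)
    mwu = sps.mannwhitneyu(x[g == "a"], x[g == "b"], method="asymptotic",
                           use_continuity=False)
    assert kw.p == pytest.approx(mwu.pvalue, abs=1e-10)


def test_kruskal_all_equal_h_zero():
    kw, dunn = kruskal_dunn(np.ones(15), np.repeat(["a", "b", "c"], 5))
    assert kw.statistic == 0.0
    assert (dunn["z"] == 0).all()


def test_dunn_detects_shifted_group():
    rng = np.random.default_rng(15)
    x = np.concatenate([rng.normal(size=30), rng.normal(size=30),
                        rng.normal(3.0, 1, size=30)])
    g = np.repeat(["a", "b", "c"], 30)
    kw, dunn = kruskal_dunn(x, g)
    assert kw.p < 1e-6
    pc = dunn.set_index(["group1", "group2"])
    assert pc.loc[("a", "c"), "p"] < 0.001
    assert pc.loc[("a", "b"), "p"] > 0.05


def partial_rank_corr_oracle(x, y, Z):
    """Independent oracle: partial correlation of ranks via the correlation
    matrix inversion identity."""
    cols = [sps.rankdata(x), sps.rankdata(y)] + \
        [sps.rankdata(Z[:, j]) for j in range(Z.shape[1])]
    R = np.corrcoef(np.array(cols))
    P = np.linalg.inv(R)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def test_conditional_spearman_matches_partial_rank_oracle():
    rng = np.random.default_rng(16)
    for _ in range(20):
        n = 50
        Z = rng.normal(size=(n, 2))
        x = Z @ [0.5, -0.3] + rng.normal(size=n)
        y = Z @ [0.2, 0.4] + 0.5 * x + rng.normal(size=n)
        res = conditional_spearman(x, y, Z)
        assert res.statistic == pytest.approx(
            partial_rank_corr_oracle(x, y, Z), abs=1e-10)


def test_conditional_spearman_reductions():
    rng = np.random.default_rng(17)
    x = rng.normal(size=40)
    y = x + 0.1 * rng.normal(size=40)
    plain = conditional_spearman(x, y)
    assert plain.statistic == pytest.approx(sps.spearmanr(x, y).statistic)
    z = rng.normal(size=(40, 1))
    assert conditional_spearman(x, np.exp(x), z).statistic > 0.99
    with pytest.raises(ValueError):
        conditional_spearman(np.ones(40), y)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_one_factor_anova_matches_ols_f():
    rng = np.random.default_rng(18)
    df = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 20),
                       "y": rng.normal(size=60)})
    df.loc[df["g"] == "c", "y"] += 1.0
    tab = anova_eta(df, "y", ["g"])
    import statsmodels.formula.api as smf

    fit = smf.ols("y ~ C(g)", df).fit()
    assert tab.loc["C(g, Sum)", "F"] == pytest.approx(fit.fvalue)
    assert tab.loc["C(g, Sum)", "PR(>F)"] == pytest.approx(fit.f_pvalue)


def test_eta2p_is_one_without_residual_variance():
    df = pd.DataFrame({"g": np.repeat(["a", "b"], 5),
                       "y": np.repeat([1.0, 2.0], 5)})
    tab = anova_eta(df, "y", ["g"])
    assert tab.loc["C(g, Sum)", "eta2p"] == pytest.approx(1.0)


def test_two_factor_anova_reports_each_effect():
    rng = np.random.default_rng(19)
    df = pd.DataFrame({
        "hap": rng.choice(["TGT", "GAG", "TGG"], 90),
        "ace": rng.choice(["yes", "no"], 90),
    })
    df["y"] = (df["hap"] == "TGT") * 0.5 + (df["ace"] == "yes") * 0.4 \
        + rng.normal(0, 0.3, 90)
    tab = anova_eta(df, "y", ["hap", "ace"])
    assert {"C(hap, Sum)", "C(ace, Sum)", "Residual"} <= set(tab.index)
    assert 0 < tab.loc["C(hap, Sum)", "eta2p"] < 1


# ---------------------------------------------------------------------------
# population genetics
# ---------------------------------------------------------------------------

def test_hwe_exact_equilibrium_counts():
    assert hwe_test((25, 50, 25)).statistic == pytest.approx(0.0)
    assert hwe_test((16, 48, 36)).statistic == pytest.approx(0.0)


def test_hwe_matches_hand_formula():
    counts = (30, 40, 30)
    n = 100
    p = (2 * 30 + 40) / 200
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array(counts)
    assert hwe_test(counts).statistic == pytest.approx(
        ((obs - exp) ** 2 / exp).sum())


def test_ld_perfect_coupling():
    res = ld_stats([[10, 0], [0, 10]])
    assert res.extra["D_prime"] == pytest.approx(1.0)
    assert res.extra["r2"] == pytest.approx(1.0)
    assert res.statistic == pytest.approx(20.0)  # N_gametes * r^2


def test_ld_monomorphic_raises():
    with pytest.raises(ValueError, match="monomorphic"):
        ld_stats([[10, 10], [0, 0]])


def ld_oracle(table):
    """Independent oracle: r^2 as the squared Pearson correlation of the two
    gamete indicator variables; chi^2 from the contingency formula; D' from
    first principles."""
    (a, b), (c, d) = table
    n = a + b + c + d
    x = np.repeat([1, 1, 0, 0], [a, b, c, d])
    y = np.repeat([1, 0, 1, 0], [a, b, c, d])
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    chi2 = sps.chi2_contingency(np.array(table), correction=False).statistic
    pA, pB = (a + b) / n, (a + c) / n
    D = a / n - pA * pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else \
        min(pA * pB, (1 - pA) * (1 - pB))
    return D, (D / dmax if dmax else 0.0), r2, chi2


@pytest.mark.parametrize("table", [
    [[5, 3], [2, 7]], [[1, 0], [0, 19]], [[4, 4], [4, 4]], [[9, 1], [1, 9]],
    [[2, 8], [7, 3]],
])
def test_ld_against_independent_oracle(table):
    res = ld_stats(table)
    D, dprime, r2, chi2 = ld_oracle(table)
    assert res.extra["D"] == pytest.approx(D)
    assert res.extra["D_prime"] == pytest.approx(dprime)
    assert res.extra["r2"] == pytest.approx(r2)
    assert res.statistic == pytest.approx(chi2)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _stepwise_data(seed=20, n=120):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 5)),
                     columns=[f"x{i}" for i in range(5)])
    y = 1.0 * X["x1"] - 0.8 * X["x3"] + rng.normal(size=n)
    return y.to_numpy(), X


def test_stepwise_matches_exhaustive_best_subset_by_aic():
    import statsmodels.api as sm

    y, X = _stepwise_data()
    sw = stepwise_select(y, X, model="ols", criterion="aic")
    best_aic, best_set = np.inf, None
    for r in range(len(X.columns) + 1):
        for combo in itertools.combinations(X.columns, r):
            Xc = sm.add_constant(X[list(combo)], has_constant="add")
            aic = sm.OLS(y, Xc).fit().aic
            if aic < best_aic:
                best_aic, best_set = aic, set(combo)
    assert set(sw.selected) == best_set


def test_stepwise_selects_true_predictor():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(1000 + seed)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=["true", "n1", "n2", "n3"])
        y = X["true"].to_numpy() + rng.normal(size=n)  # 1-SD effect
        sw = stepwise_select(y, X, model="ols")
        hits += "true" in sw.selected
    assert hits >= 38  # >= 95% of seeds


def test_stepwise_type_i_rate_near_nominal():
    selected = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(5000 + seed)
        X = pd.DataFrame({"noise": rng.normal(size=80)})
        y = rng.normal(size=80)
        sw = stepwise_select(y, X, model="ols", enter=0.05)
        selected += bool(sw.selected)
    rate = selected / n_seeds
    se = np.sqrt(0.05 * 0.95 / n_seeds)
    assert rate < 0.05 + 3 * se


def test_stepwise_keeps_forced_covariates():
    y, X = _stepwise_data()
    forced = pd.DataFrame({"age": np.arange(len(y), dtype=float)})
    sw = stepwise_select(y, X, forced=forced, model="ols")
    assert "age" in sw.forced and "age" in sw.exog.columns


# ---------------------------------------------------------------------------
# normality gate, adjustment, contingency
# ---------------------------------------------------------------------------

def test_normality_gate_passes_gaussian():
    rng = np.random.default_rng(21)
    res = normality_gate(rng.normal(size=500))
    assert res.normal and res.transform == "none"


def test_normality_gate_cubes_left_skew():
    rng = np.random.default_rng(22)
    v = rng.beta(8, 1.2, size=400)  # left-skewed, like high methylation
    res = normality_gate(v)
    assert res.transform == "cube"
    t = res.transformed
    assert ((0 <= t) & (t <= 1)).all()
    assert (np.argsort(t) == np.argsort(v)).all()  # monotone


def test_bonferroni_adjustment():
    assert adjust_pvalues([0.01], 4)[0] == pytest.approx(0.04)
    assert adjust_pvalues([0.5], 6)[0] == 1.0
    rng = np.random.default_rng(23)
    p = rng.random(50)
    from statsmodels.stats.multitest import multipletests

    oracle = multipletests(p, method="bonferroni")[1]
    assert np.allclose(adjust_pvalues(p, 50), oracle)
    with pytest.raises(ValueError):
        adjust_pvalues([1.2], 2)


def test_contingency_chisq():
    outer = np.outer([30, 70], [40, 60]) / 100.0
    assert contingency_chisq(outer).statistic == pytest.approx(0.0, abs=1e-10)
    res = contingency_chisq([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.df == 1
    # hand-computed 2x3 oracle
    table = np.array([[10.0, 20, 30], [20, 20, 20]])
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    hand = ((table - exp) ** 2 / exp).sum()
    res = contingency_chisq(table)
    assert res.statistic == pytest.approx(hand) and res.df == 2
    with pytest.raises(ValueError, match="marginal"):
        contingency_chisq([[0, 0], [5, 5]])


def test_results_summary_table():
    rng = np.random.default_rng(24)
    x = rng.normal(size=50)
    res = BootstrapOLS(2 * x + rng.normal(size=50), pd.DataFrame({"x": x}),
                       B=199, seed=0).fit()
    text = res.summary()
    assert "x" in text and "p_boot" in text and "B=199" in text
    assert res.conf_int_.loc["x", "ci_low"] <= res.params["x"] \
        <= res.conf_int_.loc["x", "ci_high"]
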