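"""Inference chain: bootstrap regressions, stepwise selection, nonparametric
tests, LD/HWE, normality gating and multiplicity adjustment.

Regression models follow the statsmodels Model/Results idiom: a
:class:`BootstrapOLS` or :class:`BootstrapLogit` is built from data and its
``fit()`` returns a results object carrying point estimates, bootstrap
standard errors, BCa 95% intervals and interval-inversion bootstrap
p-values per term, with a ``summary()`` table.  Point estimation is
delegated to statsmodels; the case-resampling BCa layer is implemented in
:mod:`allelemeth.bootstrap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .bootstrap import BootstrapCI, bca_from_replicates

__all__ = [
    "TestResult",
    "BootstrapOLS",
    "BootstrapLogit",
    "BootstrapRegressionResults",
    "stepwise_select",
    "StepwiseResult",
    "kruskal_dunn",
    "conditional_spearman",
    "anova_eta",
    "hwe_test",
    "ld_stats",
    "normality_gate",
    "adjust_pvalues",
    "contingency_chisq",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: object = None
    p: float = np.nan
    effect_size: float | None = None
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _as_design(exog, add_constant=True):
    X = pd.DataFrame(exog).copy()
    X.columns = [str(c) for c in X.columns]
    if add_constant:
        X = sm.add_constant(X, has_constant="skip")
    return X


def _drop_aliased(X: pd.DataFrame):
    """Drop columns until the design is full rank (aliased columns logged)."""
    dropped = []
    arr = X.to_numpy(float)
    while np.linalg.matrix_rank(arr) < arr.shape[1]:
        # drop the last column whose removal does not reduce the rank
        rank = np.linalg.matrix_rank(arr)
        for j in range(arr.shape[1] - 1, -1, -1):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                dropped.append(X.columns[j])
                X = X.drop(columns=[X.columns[j]])
                arr = sub
                break
    if dropped:
        warnings.warn(f"rank-deficient design: dropped aliased terms {dropped}")
    return X, dropped


# ---------------------------------------------------------------------------
# bootstrap regression models
# ---------------------------------------------------------------------------

@dataclass
class BootstrapRegressionResults:
    """Per-term estimates with BCa bootstrap uncertainty."""

    model_name: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series  # bootstrap SE
    conf_int_: pd.DataFrame  # columns ci_low, ci_high
    pvalues: pd.Series  # bootstrap (CI-inversion) p
    B: int
    alpha: float
    dropped: list[str]
    point_results: object = None  # underlying statsmodels results
    selected: pd.Series | None = None  # stepwise flags, where applicable
    warnings_: list[str] = field(default_factory=list)

    def conf_int(self) -> pd.DataFrame:
        return self.conf_int_

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "ci_low": self.conf_int_["ci_low"],
                "ci_high": self.conf_int_["ci_high"],
                "p_boot": self.pvalues,
            }
        )
        if self.selected is not None:
            out["selected"] = self.selected
        return out

    def summary(self) -> str:
        lines = [
            f"{self.model_name} — case-resampling BCa bootstrap "
            f"(B={self.B}, {100 * (1 - self.alpha):.0f}% CI)",
            "-" * 72,
            f"{'term':<22}{'beta':>10}{'se':>10}{'ci_low':>10}{'ci_high':>10}{'p_boot':>10}",
        ]
        for t in self.terms:
            lines.append(
                f"{t:<22}{self.params[t]:>10.4f}{self.bse[t]:>10.4f}"
                f"{self.conf_int_.loc[t, 'ci_low']:>10.4f}"
                f"{self.conf_int_.loc[t, 'ci_high']:>10.4f}"
                f"{self.pvalues[t]:>10.4f}"
            )
        if self.dropped:
            lines.append(f"dropped aliased terms: {self.dropped}")
        for w in self.warnings_:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class _BootstrapRegression:
    """Shared machinery for case-resampling bootstrap regressions."""

    model_name = "regression"

    def __init__(self, endog, exog, B: int = 1000, alpha: float = 0.05,
                 seed: int | None = None, add_constant: bool = True,
                 accelerated: bool = True):
        y = np.asarray(endog, dtype=float)
        X = _as_design(exog, add_constant=add_constant)
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        X, self.dropped = _drop_aliased(X)
        self.endog, self.exog = y, X
        self.B, self.alpha, self.seed = B, alpha, seed
        self.accelerated = accelerated
        self._warnings: list[str] = []

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, **kwargs):
        import patsy

        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        kwargs.setdefault("add_constant", False)
        return cls(y.iloc[:, 0], X, **kwargs)

    # subclass hooks ------------------------------------------------------
    def _point_fit(self, y, X):  # returns (params, statsmodels results | None)
        raise NotImplementedError

    def _replicate_fit(self, y, X):  # fast refit, returns params array
        raise NotImplementedError

    def fit(self, compute_p: bool = True) -> BootstrapRegressionResults:
        y, X = self.endog, self.exog
        Xa = X.to_numpy(float)
        beta_hat, point = self._point_fit(y, Xa)
        rng = np.random.default_rng(self.seed)
        n, k = Xa.shape
        theta_b = np.empty((self.B, k))
        for b in range(self.B):
            idx = rng.integers(0, n, n)
            theta_b[b] = self._replicate_fit(y[idx], Xa[idx])
        theta_jack = None
        if self.accelerated:
            theta_jack = np.empty((n, k))
            mask = np.ones(n, dtype=bool)
            for i in range(n):
                mask[i] = False
                theta_jack[i] = self._replicate_fit(y[mask], Xa[mask])
                mask[i] = True
        cis: dict[str, BootstrapCI] = {}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for j, term in enumerate(X.columns):
                cis[term] = bca_from_replicates(
                    beta_hat[j],
                    theta_b[:, j],
                    theta_jack[:, j] if theta_jack is not None else None,
                    alpha=self.alpha,
                    compute_p=compute_p,
                )
        self._warnings += [str(w.message) for w in caught]
        terms = list(X.columns)
        return BootstrapRegressionResults(
            model_name=self.model_name,
            terms=terms,
            params=pd.Series(beta_hat, index=terms),
            bse=pd.Series([cis[t].se for t in terms], index=terms),
            conf_int_=pd.DataFrame(
                {"ci_low": [cis[t].ci_low for t in terms],
                 "ci_high": [cis[t].ci_high for t in terms]},
                index=terms,
            ),
            pvalues=pd.Series(
                [np.nan if cis[t].p_value is None else cis[t].p_value for t in terms],
                index=terms,
            ),
            B=self.B,
            alpha=self.alpha,
            dropped=self.dropped,
            point_results=point,
            warnings_=list(self._warnings),
        )


class BootstrapOLS(_BootstrapRegression):
    """OLS with BCa bootstrap intervals and p-values per coefficient."""

    model_name = "OLS"

    def _point_fit(self, y, X):
        res = sm.OLS(y, X).fit()
        return np.asarray(res.params, float), res

    def _replicate_fit(self, y, X):
        return np.linalg.lstsq(X, y, rcond=None)[0]


class BootstrapLogit(_BootstrapRegression):
    """Logistic regression (IRLS/Newton point fit) with BCa bootstrap."""

    model_name = "Logit"

    def _point_fit(self, y, X):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y, X).fit(disp=0)
            except Exception:
                res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
        for w in caught:
            if "separation" in str(w.message).lower():
                self._warnings.append(f"possible separation: {w.message}")
        return np.asarray(res.params, float), res

    def _replicate_fit(self, y, X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return np.asarray(sm.Logit(y, X).fit(disp=0).params, float)
            except Exception:
                try:
                    return np.asarray(
                        sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=100).params,
                        float,
                    )
                except Exception:
                    return np.full(X.shape[1], np.nan)


def fit_ols(y, design, **kwargs) -> BootstrapRegressionResults:
    """Convenience: ``BootstrapOLS(y, design, **kwargs).fit()``."""
    return BootstrapOLS(y, design, **kwargs).fit()


def fit_logistic(y, design, **kwargs) -> BootstrapRegressionResults:
    return BootstrapLogit(y, design, **kwargs).fit()


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    selected: list[str]
    forced: list[str]
    path: list[str]
    results: object  # final statsmodels results
    exog: pd.DataFrame

    @property
    def terms(self) -> list[str]:
        return list(self.exog.columns)


def _sm_fit(y, X, model):
    if model == "ols":
        return sm.OLS(y, X).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.Logit(y, X).fit(disp=0)
        except Exception:
            return sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)


def stepwise_select(
    y,
    candidates: pd.DataFrame,
    forced: pd.DataFrame | None = None,
    model: str = "ols",
    direction: str = "both",
    criterion: str = "pvalue",
    enter: float = 0.05,
    remove: float = 0.10,
    max_iter: int = 50,
) -> StepwiseResult:
    """Forward-backward stepwise selection.

    ``criterion="pvalue"`` enters the candidate with the smallest Wald p
    below ``enter`` and removes selected terms whose p exceeds ``remove``;
    ``criterion="aic"`` adds/removes whichever single change most improves
    AIC.  Forced covariates (and the intercept) are never removed.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidate predictors supplied")
    y = np.asarray(y, dtype=float)
    forced = pd.DataFrame(index=candidates.index) if forced is None else pd.DataFrame(forced)
    base = sm.add_constant(forced.copy(), has_constant="skip")
    base, _ = _drop_aliased(base)
    selected: list[str] = []
    path: list[str] = []

    def build(terms):
        return pd.concat([base, candidates[terms]], axis=1)

    for _ in range(max_iter):
        changed = False
        # forward
        if direction in ("both", "forward"):
            remaining = [c for c in candidates.columns if c not in selected]
            best, best_score = None, None
            cur_aic = _sm_fit(y, build(selected).to_numpy(float), model).aic
            for c in remaining:
                X = build(selected + [c])
                if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
                    continue
                res = _sm_fit(y, X.to_numpy(float), model)
                if criterion == "pvalue":
                    p = res.pvalues[X.columns.get_loc(c)]
                    if p < enter and (best_score is None or p < best_score):
                        best, best_score = c, p
                else:
                    if res.aic < cur_aic - 1e-9 and (
                        best_score is None or res.aic < best_score
                    ):
                        best, best_score = c, res.aic
            if best is not None:
                selected.append(best)
                path.append(f"+{best}")
                changed = True
        # backward
        if direction in ("both", "backward") and selected:
            X = build(selected)
            res = _sm_fit(y, X.to_numpy(float), model)
            if criterion == "pvalue":
                ps = {c: res.pvalues[X.columns.get_loc(c)] for c in selected}
                worst = max(ps, key=ps.get)
                if ps[worst] > remove:
                    selected.remove(worst)
                    path.append(f"-{worst}")
                    changed = True
            else:
                cur_aic = res.aic
                best, best_aic = None, cur_aic
                for c in selected:
                    rest = [t for t in selected if t != c]
                    r = _sm_fit(y, build(rest).to_numpy(float), model)
                    if r.aic < best_aic - 1e-9:
                        best, best_aic = c, r.aic
                if best is not None:
                    selected.remove(best)
                    path.append(f"-{best}")
                    changed = True
        if not changed:
            break

    X = build(selected)
    res = _sm_fit(y, X.to_numpy(float), model)
    return StepwiseResult(
        selected=selected, forced=list(base.columns), path=path, results=res, exog=X
    )


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def kruskal_dunn(values, groups) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) plus pairwise Dunn z tests.

    Dunn p-values are two-sided and unadjusted; family-wise adjustment is the
    caller's responsibility.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:
        kw = TestResult("kruskal", 0.0, len(labels) - 1, 1.0)
    else:
        h, p = sps.kruskal(*samples)
        kw = TestResult("kruskal", float(h), len(labels) - 1, float(p))

    ranks = sps.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            ni, nj = (groups == gi).sum(), (groups == gj).sum()
            diff = ranks[groups == gi].mean() - ranks[groups == gj].mean()
            var = base_var * (1.0 / ni + 1.0 / nj)
            z = diff / np.sqrt(var) if var > 0 else 0.0
            rows.append(
                {"group1": gi, "group2": gj, "z": float(z),
                 "p": float(2 * sps.norm.sf(abs(z)))}
            )
    return kw, pd.DataFrame(rows)


def conditional_spearman(x, y, conditioners=None) -> TestResult:
    """Spearman correlation, optionally partialled on conditioners.

    All variables are rank-transformed; conditioners are regressed out of the
    ranks by least squares and the Pearson correlation of the residuals is
    reported, with a t approximation on n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    n = len(x)
    if conditioners is None or (hasattr(conditioners, "shape") and np.size(conditioners) == 0):
        rho, p = sps.spearmanr(x, y)
        return TestResult("spearman", float(rho), n - 2, float(p), extra={"n": n})
    Z = np.column_stack([np.asarray(c, dtype=float) for c in np.atleast_2d(np.asarray(conditioners).T).T]) \
        if np.ndim(conditioners) == 1 else np.asarray(conditioners, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the number of conditioners")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    Zr = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(k)])
    res_x = rx - Zr @ np.linalg.lstsq(Zr, rx, rcond=None)[0]
    res_y = ry - Zr @ np.linalg.lstsq(Zr, ry, rcond=None)[0]
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    df = n - 2 - k
    t = rho * np.sqrt(df / max(1e-12, 1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult("conditional_spearman", rho, df, p, extra={"n": n, "k": k})


def anova_eta(
    data: pd.DataFrame,
    dv: str,
    factors: list[str],
    covariates: list[str] | None = None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Type-III ANOVA (sum-coded factors) with partial eta squared per effect.

    eta2p = SS_effect / (SS_effect + SS_residual).
    """
    terms = [f"C({f}, Sum)" for f in factors]
    if interaction and len(factors) > 1:
        terms.append(":".join(f"C({f}, Sum)" for f in factors))
    terms += list(covariates or [])
    formula = f"{dv} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    ss_resid = tab.loc["Residual", "sum_sq"]
    out = tab.drop(index=["Intercept"], errors="ignore").copy()
    out["eta2p"] = out["sum_sq"] / (out["sum_sq"] + ss_resid)
    out.loc["Residual", "eta2p"] = np.nan
    return out


# ---------------------------------------------------------------------------
# population genetics
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts) -> TestResult:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts``: (n_AA, n_Aa, n_aa).
    """
    n_aa_, n_ab, n_bb = (float(c) for c in genotype_counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("empty genotype table")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    q = 1 - p
    expected = np.array([n * p**2, 2 * n * p * q, n * q**2])
    observed = np.array([n_aa_, n_ab, n_bb])
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(contrib.sum())
    return TestResult("hwe", chi2, 1, float(sps.chi2.sf(chi2, 1)),
                      extra={"allele_freq": p})


def ld_stats(haplotype_counts) -> TestResult:
    """Pairwise LD from a 2x2 gamete-count table [[AB, Ab], [aB, ab]].

    D = p_AB - p_A p_B; D' = D / D_max (sign-appropriate bound);
    r^2 = D^2 / (p_A p_a p_B p_b); chi^2 = N_gametes * r^2 (1 df).
    """
    t = np.asarray(haplotype_counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 gamete-count table")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    p_ab = t[0, 0] / n
    p_a = t[0].sum() / n
    p_b = t[:, 0].sum() / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else d / d_max
    r2 = d**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    chi2 = n * r2
    return TestResult(
        "ld", chi2, 1, float(sps.chi2.sf(chi2, 1)),
        extra={"D": float(d), "D_prime": float(d_prime), "r2": float(r2), "n_gametes": float(n)},
    )


# ---------------------------------------------------------------------------
# gates and adjustments
# ---------------------------------------------------------------------------

@dataclass
class NormalityGateResult:
    normal: bool
    transform: str  # "none" | "cube"
    values: np.ndarray
    transformed: np.ndarray | None
    ks: TestResult
    ks_after: TestResult | None

    @property
    def analysis_values(self) -> np.ndarray:
        return self.values if self.transform == "none" else self.transformed


def normality_gate(values, alpha: float = 0.05) -> NormalityGateResult:
    """One-sample KS test against a fitted normal; on rejection with left
    skew, apply the cube transform (x^3) and re-test.

    The cube maps [0,1] into [0,1] monotonically, pushing a left-skewed
    methylation distribution toward symmetry.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 8:
        raise ValueError("need at least 8 observations")
    stat, p = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    ks = TestResult("ks", float(stat), None, float(p))
    if p >= alpha:
        return NormalityGateResult(True, "none", v, None, ks, None)
    if sps.skew(v) < 0:
        t = v**3
        stat2, p2 = sps.kstest(t, "norm", args=(t.mean(), t.std(ddof=1)))
        ks2 = TestResult("ks", float(stat2), None, float(p2))
        return NormalityGateResult(p2 >= alpha, "cube", v, t, ks, ks2)
    return NormalityGateResult(False, "none", v, None, ks, None)


def adjust_pvalues(pvals, family_size: int):
    """Bonferroni: p_adj = min(1, p * family_size)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * family_size)


def contingency_chisq(table) -> TestResult:
    """Pearson chi-square of a two-way table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(t, correction=False)
    return TestResult("chi2", float(res.statistic), int(res.dof), float(res.pvalue))
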