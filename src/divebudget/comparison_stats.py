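"""Statistical contrasts between solar periods and between survey methods.

Behavior proportions are compared diurnal-vs-nocturnal with Wilcoxon rank-sum
tests (normal approximation with tie and continuity correction, r = |Z|/sqrt(N)
effect size) and with binomial models of the behavior indicator on period —
a plain GLM, or a mixed model with a per-bird random intercept to absorb
individual repeatability. Energy-expenditure estimates from the two survey
methods (accelerometry vs instantaneous scans) are compared with Welch
two-sample t-tests and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_size: float
    n_a: int
    n_b: int
    method: str
    flagged: bool = False


def rank_sum_test(group_a, group_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small tie-free samples, otherwise the
    normal approximation with tie and continuity correction (mirroring the
    R ``wilcox.test`` defaults); effect size r = |Z| / sqrt(n_a + n_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    n = len(a) + len(b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, 0.0, len(a), len(b), "rank_sum", flagged=True)
    has_ties = len(np.unique(pooled)) < n
    method = "asymptotic" if has_ties or max(len(a), len(b)) >= 50 else "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method=method, use_continuity=True)
    # recover |Z| from the two-sided p of the normal approximation
    z = abs(sps.norm.ppf(res.pvalue / 2.0)) if res.pvalue < 1.0 else 0.0
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        effect_size=float(z / np.sqrt(n)), n_a=len(a), n_b=len(b),
        method="rank_sum",
    )


@dataclass(frozen=True)
class BinomialModelResult:
    coefficient: float  # log-odds of the behavior for period 'diurnal' vs base
    p_value: float | None
    random_intercept: bool
    separated: bool
    n_groups: int


def binomial_period_model(
    table: pd.DataFrame, random_intercept: bool = False
) -> BinomialModelResult:
    """Logistic model of a behavior indicator on solar period.

    ``table`` has one row per bird x period with columns bird_id, period
    ('diurnal'/'nocturnal'), successes, failures. The returned coefficient is
    the log-odds difference diurnal - nocturnal; positive means the behavior
    is more frequent by day. With ``random_intercept`` a per-bird random
    intercept is added (variational Bayes fit; p from the posterior normal
    approximation). Complete separation is flagged and no p is reported.
    """
    import statsmodels.api as sm

    req = {"bird_id", "period", "successes", "failures"}
    if not req <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(req)}")
    periods = sorted(table["period"].unique())
    if len(periods) < 2:
        raise ValueError("need >= 2 periods")
    tot = table.groupby("period")[["successes", "failures"]].sum()
    if (tot["successes"] == 0).any() or (tot["failures"] == 0).any():
        return BinomialModelResult(
            coefficient=float("nan"), p_value=None,
            random_intercept=random_intercept, separated=True,
            n_groups=table["bird_id"].nunique(),
        )
    x = (table["period"] == "diurnal").astype(float)
    if not random_intercept:
        X = sm.add_constant(x.to_numpy())
        endog = table[["successes", "failures"]].to_numpy(dtype=float)
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        return BinomialModelResult(
            coefficient=float(fit.params[1]), p_value=float(fit.pvalues[1]),
            random_intercept=False, separated=False,
            n_groups=table["bird_id"].nunique(),
        )
    if table["bird_id"].nunique() < 5:
        raise ValueError("random-intercept model needs >= 5 birds")
    # expand binomial rows to Bernoulli for the mixed-model fit
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    reps = (table["successes"] + table["failures"]).astype(int)
    df = pd.DataFrame({
        "y": np.concatenate([
            np.r_[np.ones(int(s)), np.zeros(int(f))]
            for s, f in zip(table["successes"], table["failures"])
        ]),
        "diurnal": np.repeat(x.to_numpy(), reps),
        "bird": np.repeat(table["bird_id"].astype(str).to_numpy(), reps),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            "y ~ diurnal", {"bird": "0 + C(bird)"}, df
        )
        fit = model.fit_vb()
    i = list(fit.model.exog_names).index("diurnal")
    coef = float(fit.fe_mean[i])
    sd = float(fit.fe_sd[i])
    z = coef / sd
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return BinomialModelResult(
        coefficient=coef, p_value=p, random_intercept=True, separated=False,
        n_groups=table["bird_id"].nunique(),
    )


def two_tailed_t(sample_a, sample_b) -> TestResult:
    """Welch's two-sample t-test (two-sided) with Cohen's d effect size."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        same = a.mean() == b.mean()
        return TestResult(0.0 if same else np.inf, 1.0 if same else 0.0,
                          0.0 if same else np.inf, len(a), len(b),
                          "welch_t", flagged=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.inf
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        effect_size=float(d), n_a=len(a), n_b=len(b), method="welch_t",
    )
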