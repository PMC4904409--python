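"""Group comparisons and wind-shear response models.

Two-group Mann-Whitney-Wilcoxon tests, ANCOVA (factor effect given a
covariate, Type-II sums of squares), binning of adult-juvenile climb-rate
differences over wind shear, and AICc selection among a constant, linear and
quadratic (hump-shaped) response model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .config import StatsConfig

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Result of a two-group test (U or F) with per-group summaries."""

    test: str
    statistic: float
    p_value: float
    group_means: dict
    group_ses: dict
    ns: dict


def _mean_se(a):
    a = np.asarray(a, dtype=float)
    se = float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else np.nan
    return float(np.mean(a)), se


def mww_test(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney-Wilcoxon test.

    U is the rank-sum statistic of ``x`` with midranks for ties.  The p-value
    is exact (full enumeration) for small tie-free samples (n1*n2 <= 400),
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.r_[x, y]
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        p = 1.0
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (not has_ties and len(x) * len(y) <= 400) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(res.pvalue)
    mx, sex = _mean_se(x)
    my, sey = _mean_se(y)
    return GroupComparison(
        test="MWW", statistic=u, p_value=float(min(p, 1.0)),
        group_means={"x": mx, "y": my}, group_ses={"x": sex, "y": sey},
        ns={"x": len(x), "y": len(y)},
    )


def ancova(
    response: Sequence[float],
    covariate: Sequence[float],
    factor: Sequence,
) -> GroupComparison:
    """Factor effect on the response controlling for a covariate.

    Fits ``response ~ C(factor) + covariate`` by OLS and reports the Type-II
    F test of the factor term.
    """
    df = pd.DataFrame({
        "response": np.asarray(response, dtype=float),
        "covariate": np.asarray(covariate, dtype=float),
        "factor": list(factor),
    })
    levels = df["factor"].unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels")
    if df["covariate"].nunique() < 2:
        raise ValueError("covariate does not vary")
    model = smf.ols("response ~ C(factor) + covariate", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    frow = table.loc["C(factor)"]
    means = {}
    ses = {}
    ns = {}
    for lv in levels:
        m, se = _mean_se(df.loc[df["factor"] == lv, "response"])
        means[lv], ses[lv], ns[lv] = m, se, int((df["factor"] == lv).sum())
    return GroupComparison(
        test="ANCOVA-F", statistic=float(frow["F"]), p_value=float(frow["PR(>F)"]),
        group_means=means, group_ses=ses, ns=ns,
    )


def bin_climb_difference(
    thermals: pd.DataFrame,
    bin_width: float = 1.0,
    config: Optional[StatsConfig] = None,
) -> pd.DataFrame:
    """Adult-minus-juvenile mean climb-rate difference per wind-shear bin.

    ``thermals`` needs columns ``climb_rate``, ``wind_shear`` and
    ``age_class`` in {"adult", "juvenile"}.  Bins missing one class are
    dropped (logged).  Returns shear bin centre, difference, its SE and the
    per-class counts.
    """
    cfg = config or StatsConfig(shear_bin_width=bin_width)
    w = cfg.shear_bin_width
    df = thermals.copy()
    df["bin"] = np.floor(df["wind_shear"].to_numpy(dtype=float) / w).astype(int)
    rows = []
    for b, grp in df.groupby("bin"):
        ad = grp.loc[grp["age_class"] == "adult", "climb_rate"]
        ju = grp.loc[grp["age_class"] == "juvenile", "climb_rate"]
        if len(ad) == 0 or len(ju) == 0:
            log.info("shear bin %s dropped: only one age class present", b)
            continue
        ma, sa = _mean_se(ad)
        mj, sj = _mean_se(ju)
        se = float(np.sqrt((sa if np.isfinite(sa) else 0.0) ** 2
                           + (sj if np.isfinite(sj) else 0.0) ** 2))
        rows.append({
            "shear": (b + 0.5) * w, "difference": ma - mj, "se": se,
            "n_adult": len(ad), "n_juvenile": len(ju),
        })
    return pd.DataFrame(rows)


@dataclass
class ModelFit:
    """One polynomial fit of the shear-difference response."""

    model: str  # "none" | "linear" | "quadratic"
    coefficients: np.ndarray  # ascending powers (c0, c1, c2)
    rss: float
    n: int
    k: int  # number of regression coefficients
    aicc: float
    adjusted_r2: float

    @property
    def quadratic_coefficient(self) -> float:
        return float(self.coefficients[2]) if len(self.coefficients) > 2 else 0.0


def aicc_from_rss(n: int, rss: float, k: int) -> float:
    """AICc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1) (Gaussian RSS form)."""
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k)."""
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k))


_MODELS = (("none", 0), ("linear", 1), ("quadratic", 2))


def fit_shear_models(
    shear: Sequence[float],
    difference: Sequence[float],
) -> tuple[list[ModelFit], ModelFit]:
    """Least-squares fits of constant / linear / hump-shaped responses.

    Returns the list of fits and the AICc-selected one.  A model whose
    parameter count leaves no AICc degrees of freedom (n <= k + 1) is
    skipped with a log message.
    """
    x = np.asarray(shear, dtype=float)
    y = np.asarray(difference, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 bins to compare models")
    tss = float(np.sum((y - y.mean()) ** 2))
    fits: list[ModelFit] = []
    for name, deg in _MODELS:
        k = deg + 1
        if n <= k + 1:
            log.info("model %s skipped: n=%d leaves no AICc degrees of freedom", name, n)
            continue
        coef = np.polynomial.polynomial.polyfit(x, y, deg)
        pred = np.polynomial.polynomial.polyval(x, coef)
        rss = float(np.sum((y - pred) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        fits.append(ModelFit(
            model=name, coefficients=np.atleast_1d(coef), rss=rss, n=n, k=k,
            aicc=aicc_from_rss(n, rss, k),
            adjusted_r2=adjusted_r2(r2, n, k),
        ))
    if not fits:
        raise ValueError("no model could be fit")
    selected = min(fits, key=lambda f: f.aicc)
    return fits, selected


def model_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Model-comparison table (function, adjusted R2, AICc)."""
    rows = []
    for f in fits:
        c = np.zeros(3)
        c[: len(f.coefficients)] = f.coefficients
        if f.model == "none":
            fn = f"y = {c[0]:.3f}"
        elif f.model == "linear":
            fn = f"y = {c[1]:.3f}x + {c[0]:.3f}"
        else:
            fn = f"y = {c[2]:.3f}x^2 + {c[1]:.3f}x + {c[0]:.3f}"
        rows.append({"model": f.model, "function": fn,
                     "adjusted_r2": round(f.adjusted_r2, 3), "aicc": round(f.aicc, 3)})
    return pd.DataFrame(rows)
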