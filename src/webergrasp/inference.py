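"""Statistical inference on per-subject slope measures.

Contrasts between feedback conditions use paired or Welch t-tests with
Cohen's d.  Multi-level comparisons use a linear mixed model with
by-subject random intercepts and a Wald chi-square for the condition main
effect.  Whether the apparent Weber fraction differs from zero is assessed
with a JZS Bayes factor: a one-sample t-test against a point null with a
zero-centered Cauchy prior on the standardized effect size, which can
quantify evidence for absence as well as presence of Weber scaling.  A
quadratic-coefficient convexity index captures nonlinearity of the
response-versus-size mapping.

All tests are two-sided and no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import (
    DegenerateContrastError,
    InvalidParameterError,
    NumericalError,
    UndefinedSlopeError,
)

__all__ = [
    "ContrastResult",
    "AnovaResult",
    "BayesResult",
    "ConvexityIndex",
    "paired_contrast",
    "group_contrast",
    "condition_anova",
    "jzs_bayes_factor",
    "bf10_from_t",
    "rscale_sensitivity",
    "adherence_decision",
    "convexity_index",
]

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0  # ~0.707


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float
    cohen_d: float

    def to_json(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AnovaResult:
    coefficients: dict  # level -> {"estimate", "se"} versus the reference level
    reference_level: str
    chi2: float
    df: int
    p: float
    eta_squared: float
    warnings: list = field(default_factory=list)

    def to_json(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    rscale: float
    n: int
    t: float

    def to_json(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ConvexityIndex:
    subject: object
    condition: object
    quadratic_coef: float  # mm^-1
    label: str  # convex / linear / concave

    def to_json(self) -> dict:
        return asdict(self)


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidParameterError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} contains non-finite values")
    return arr


def paired_contrast(values_a, values_b) -> ContrastResult:
    """Paired t-test on within-subject differences ``a - b``.

    Cohen's d is the mean difference over the SD of the differences.  A
    non-zero constant shift (zero difference variance) is degenerate; two
    identical vectors return a zero contrast.
    """
    a = _as_array(values_a, "values_a")
    b = _as_array(values_b, "values_b")
    if len(a) != len(b):
        raise InvalidParameterError("paired samples must have equal length")
    if len(a) < 2:
        raise InvalidParameterError("paired contrast needs at least 2 pairs")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    n = len(diff)
    if sd == 0.0:
        if mean == 0.0:
            return ContrastResult(0.0, 0.0, 0.0, n - 1, 1.0, 0.0)
        raise DegenerateContrastError(
            "differences have zero variance but non-zero mean; t undefined"
        )
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return ContrastResult(mean, se, t, n - 1, float(p), mean / sd)


def group_contrast(values_g1, values_g2) -> ContrastResult:
    """Welch two-sample t-test on independent groups (``g1 - g2``).

    Cohen's d uses the pooled SD.
    """
    g1 = _as_array(values_g1, "values_g1")
    g2 = _as_array(values_g2, "values_g2")
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    n1, n2 = len(g1), len(g2)
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    estimate = float(g1.mean() - g2.mean())
    if pooled_var == 0.0:
        if estimate == 0.0:
            return ContrastResult(0.0, 0.0, 0.0, n1 + n2 - 2, 1.0, 0.0)
        raise DegenerateContrastError("zero pooled variance with non-zero mean difference")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    se = math.sqrt(v1 / n1 + v2 / n2)
    return ContrastResult(
        estimate, se, float(res.statistic), float(res.df), float(res.pvalue),
        estimate / math.sqrt(pooled_var),
    )


def condition_anova(
    long: pd.DataFrame,
    measure: str = "weber_fraction",
    condition: str = "condition",
    subject: str = "subject",
) -> AnovaResult:
    """Condition main effect from a random-intercept linear mixed model.

    Fits ``measure ~ condition`` with a by-subject random intercept (REML)
    and reports per-level coefficients versus the reference level (first
    level in sorted order), a Wald chi-square for the joint condition
    effect, and an eta-squared computed as the sum of squares of the
    fixed-effect condition predictions over the total sum of squares.

    Subjects with missing cells are dropped listwise, with a warning
    recorded in the result.
    """
    import statsmodels.formula.api as smf

    for col in (measure, condition, subject):
        if col not in long.columns:
            raise InvalidParameterError(f"column '{col}' not found in table")
    data = long[[subject, condition, measure]].dropna().copy()
    levels = sorted(data[condition].astype(str).unique())
    if len(levels) < 2:
        raise InvalidParameterError("need at least 2 conditions")

    notes = []
    counts = data.groupby(subject)[condition].nunique()
    complete = counts[counts == len(levels)].index
    if len(complete) < len(counts):
        dropped = sorted(set(counts.index) - set(complete))
        notes.append(f"dropped subjects with missing cells: {dropped}")
        data = data[data[subject].isin(complete)]
    if data[subject].nunique() < 2:
        raise InvalidParameterError("need at least 2 complete subjects")

    data = data.rename(columns={measure: "_y", condition: "_cond", subject: "_subj"})
    # degenerate case: no within-subject variation across conditions at all
    # (zero residual variance would break the mixed-model fit)
    if (data.groupby("_subj")["_y"].nunique() == 1).all():
        return AnovaResult(
            coefficients={lev: {"estimate": 0.0, "se": 0.0} for lev in levels[1:]},
            reference_level=levels[0],
            chi2=0.0,
            df=len(levels) - 1,
            p=1.0,
            eta_squared=0.0,
            warnings=notes + ["no within-subject variation; trivial zero effect"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("_y ~ C(_cond)", data, groups=data["_subj"]).fit(reml=True)

    coef_names = [name for name in fit.fe_params.index if name.startswith("C(_cond)")]
    coefficients = {}
    for name in coef_names:
        level = name.split("[T.", 1)[1].rstrip("]")
        coefficients[level] = {
            "estimate": float(fit.fe_params[name]),
            "se": float(fit.bse_fe[name]),
        }
    if all(fit.fe_params[name] == 0.0 for name in coef_names):
        chi2, p = 0.0, 1.0
    else:
        wald = fit.wald_test(" = 0, ".join(coef_names) + " = 0", scalar=True)
        chi2, p = float(wald.statistic), float(wald.pvalue)

    y = data["_y"].to_numpy()
    fixed_pred = fit.model.exog @ fit.fe_params.to_numpy()
    ss_effect = float(np.sum((fixed_pred - y.mean()) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta2 = ss_effect / ss_total if ss_total > 0 else 0.0
    return AnovaResult(
        coefficients=coefficients,
        reference_level=levels[0],
        chi2=chi2,
        df=len(coef_names),
        p=p,
        eta_squared=min(eta2, 1.0),
        warnings=notes,
    )


def bf10_from_t(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> float:
    """JZS Bayes factor (H1 over point null) from a one-sample t statistic.

    The marginal likelihood under H1 integrates the noncentral-t likelihood
    over the Cauchy(0, rscale) prior on the standardized effect size delta.
    The substitution ``delta = rscale * tan(theta)`` maps the real line to
    (-pi/2, pi/2) and absorbs the Cauchy density into a constant 1/pi,
    leaving a smooth bounded integrand for adaptive quadrature.  Marginal
    likelihoods are resolved to 1e-8 absolute.
    """
    if n < 2:
        raise InvalidParameterError(f"need n >= 2, got {n}")
    if not rscale > 0:
        raise InvalidParameterError(f"rscale must be > 0, got {rscale}")
    if not math.isfinite(t):
        raise InvalidParameterError("t statistic must be finite")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(theta: float) -> float:
        delta = rscale * math.tan(theta)
        return stats.nct.pdf(t, nu, delta * sqrt_n) / math.pi

    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            marg_h1, err = integrate.quad(
                integrand, -math.pi / 2, math.pi / 2,
                epsabs=1e-12, epsrel=1e-10, limit=200,
            )
        except integrate.IntegrationWarning as exc:
            raise NumericalError(f"JZS integration failed to converge: {exc}") from exc
    if err > 1e-8:
        raise NumericalError(f"JZS integration error {err:.3g} exceeds 1e-8")
    marg_h0 = stats.t.pdf(t, nu)
    if marg_h0 == 0.0 or marg_h1 <= 0.0:
        raise NumericalError("marginal likelihood underflow; |t| too extreme")
    return marg_h1 / marg_h0


def jzs_bayes_factor(
    values, null_value: float = 0.0, rscale: float = DEFAULT_RSCALE
) -> BayesResult:
    """One-sample JZS Bayes factor that the mean differs from ``null_value``."""
    x = _as_array(values, "values")
    if len(x) < 2:
        raise InvalidParameterError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0 or np.ptp(x) == 0.0:
        raise DegenerateContrastError("zero variance; t statistic undefined")
    n = len(x)
    t = float((x.mean() - null_value) / (sd / math.sqrt(n)))
    return BayesResult(bf10=bf10_from_t(t, n, rscale), rscale=rscale, n=n, t=t)


def rscale_sensitivity(
    values,
    rscales: Sequence[float] = (0.5, DEFAULT_RSCALE, 1.0),
    null_value: float = 0.0,
) -> list:
    """Bayes factors for the same data under several prior scales."""
    rscales = list(rscales)
    if not rscales:
        raise InvalidParameterError("rscales must be non-empty")
    return [jzs_bayes_factor(values, null_value=null_value, rscale=r) for r in rscales]


def adherence_decision(
    bayes: BayesResult, lower: float = 1.0 / 3.0, upper: float = 3.0
) -> str:
    """Classify evidence for Weber scaling from a Bayes factor.

    ``present`` if ``bf10 >= upper``, ``absent`` if ``bf10 <= lower``,
    otherwise ``anecdotal``.
    """
    if not lower < upper:
        raise InvalidParameterError(f"cutoffs inverted: lower={lower}, upper={upper}")
    if bayes.bf10 >= upper:
        return "present"
    if bayes.bf10 <= lower:
        return "absent"
    return "anecdotal"


def convexity_index(
    sizes,
    mean_responses,
    subject=None,
    condition=None,
    tol: float = 1e-8,
) -> ConvexityIndex:
    """Quadratic coefficient of the mean response versus size.

    A positive coefficient labels the mapping ``convex``, negative
    ``concave``, and within ``tol`` of zero ``linear``.  Requires at least
    three distinct sizes.
    """
    s = _as_array(sizes, "sizes")
    y = _as_array(mean_responses, "mean_responses")
    if len(np.unique(s)) < 3:
        raise UndefinedSlopeError("convexity index needs >= 3 distinct sizes")
    coef = float(np.polyfit(s, y, 2)[0])
    if abs(coef) <= tol:
        label = "linear"
    else:
        label = "convex" if coef > 0 else "concave"
    return ConvexityIndex(subject=subject, condition=condition, quadratic_coef=coef, label=label)
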