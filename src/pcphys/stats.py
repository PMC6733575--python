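"""Group statistics: two-sample t tests, t-test power/sample size, and
one-within-factor repeated-measures ANOVA.

Cell- and mouse-level comparisons in this kind of study are reported as
mean ± SD with a two-tailed Student's t test, so the t statistic is
reconstructable from printed summaries alone; :func:`t_from_summary`
does exactly that and :func:`t_from_raw` agrees with it algebraically.
A priori sample sizes for two-sample designs come from the noncentral-t
power function (:func:`sample_size_t`).  Eye-movement and locomotion
learning curves are compared with a repeated-measures ANOVA
(:func:`rm_anova`), sphericity assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ContractError, SpecificationError, UnbalancedDesignError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "PowerSpec",
    "RMAnovaResult",
    "t_from_summary",
    "t_from_raw",
    "power_two_sample_t",
    "sample_size_t",
    "rm_anova",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD over n units (cells or mice) for one group."""

    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ContractError(f"group '{self.label}': n must be >= 2")
        if self.sd < 0:
            raise ContractError(f"group '{self.label}': sd must be >= 0")


@dataclass
class TTestResult:
    t: float
    df: float       # fractional for Welch
    p: float        # two-tailed
    method: str     # pooled | welch


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample t-test sample-size calculation.

    ``delta`` is the minimal relevant difference and ``sd`` the expected
    common SD, both in the measured units; power = 1 − beta.
    """

    delta: float
    sd: float
    alpha: float = 0.05
    beta: float = 0.20
    test: str = "two_sample_t"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise SpecificationError("alpha: must be in (0, 1)")
        if not (0 < self.beta < 1):
            raise SpecificationError("beta: must be in (0, 1)")
        if self.delta <= 0:
            raise SpecificationError("delta: must be > 0")
        if self.sd <= 0:
            raise SpecificationError("sd: must be > 0")
        if self.test != "two_sample_t":
            raise SpecificationError("test: only 'two_sample_t' is supported")

    @property
    def effect_size(self) -> float:
        return self.delta / self.sd


@dataclass
class RMAnovaResult:
    F: float
    df_condition: int
    df_error: int
    p: float


# ---------------------------------------------------------------------------
# t tests


def t_from_summary(a: GroupSummary, b: GroupSummary,
                   method: str = "pooled") -> TTestResult:
    """Two-tailed two-sample t test from (mean, SD, n) summaries.

    ``pooled`` (classic Student) uses the pooled variance with
    df = n_a + n_b − 2; ``welch`` uses unpooled variances with the
    Welch–Satterthwaite df.  The sign follows the order of arguments
    (a − b).
    """
    if method not in ("pooled", "welch"):
        raise ContractError(f"unknown method '{method}'")
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=(method == "pooled"))
    if method == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue), method=method)


def t_from_raw(a, b, method: str = "pooled") -> TTestResult:
    """Two-sample t test from raw observations.

    Identical, by construction, to :func:`t_from_summary` applied to the
    sample summaries (sample SD, ddof=1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each sample needs n >= 2")
    return t_from_summary(
        GroupSummary(mean=float(a.mean()), sd=float(a.std(ddof=1)), n=a.size),
        GroupSummary(mean=float(b.mean()), sd=float(b.std(ddof=1)), n=b.size),
        method=method)


# ---------------------------------------------------------------------------
# Power / sample size


def power_two_sample_t(n_per_group: int, effect_size: float,
                       alpha: float = 0.05) -> float:
    """Power of the two-tailed two-sample t test at per-group size n.

    Under the alternative, the t statistic follows a noncentral t
    distribution with df = 2n − 2 and noncentrality d·√(n/2); power is
    the probability of |T| exceeding the two-tailed critical value.
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = effect_size * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_t(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n achieving the target power.

    Incremental search from n = 2 (the smallest n with positive df)
    using :func:`power_two_sample_t` at effect size d = delta / sd.
    """
    target = 1.0 - spec.beta
    d = spec.effect_size
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, d, spec.alpha) >= target:
            return n
    raise SpecificationError(
        f"delta/sd: no n <= {n_max} reaches power {target}")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def rm_anova(table) -> RMAnovaResult:
    """One-within-factor repeated-measures ANOVA (sphericity assumed).

    ``table`` is a complete, balanced subjects × conditions array (or
    DataFrame with subjects as rows).  The F statistic is
    MS_condition / MS_error after removing the subject effect:

        SS_error = SS_total − SS_subjects − SS_conditions
        F = (SS_cond / (c−1)) / (SS_error / ((c−1)(s−1)))

    A table with zero condition variance returns F = 0, p = 1.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ContractError("need >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise UnbalancedDesignError("missing cells in the repeated-measures table")
    s, c = x.shape
    grand = x.mean()
    ss_subj = c * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = s * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df_c, df_e = c - 1, (c - 1) * (s - 1)
    if ss_cond <= 1e-12 * max(ss_tot, 1.0):
        return RMAnovaResult(F=0.0, df_condition=df_c, df_error=df_e, p=1.0)
    ms_c = ss_cond / df_c
    ms_e = ss_err / df_e
    if ms_e <= 0:
        # zero residual variance with a real condition effect
        return RMAnovaResult(F=np.inf, df_condition=df_c, df_error=df_e, p=0.0)
    F = float(ms_c / ms_e)
    return RMAnovaResult(F=F, df_condition=df_c, df_error=df_e,
                         p=float(sps.f.sf(F, df_c, df_e)))
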