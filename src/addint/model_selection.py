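"""Interaction detection by comparing constrained and unconstrained fits.

The unconstrained model M1 and the additive-null model M2 are nested and
differ by one degree of freedom (the single constraint equation).  They
are compared with the generalized Akaike information criterion

    GAIC(kappa) = GDEV + kappa * df,

where kappa = 2 gives AIC, kappa = ln(n) gives BIC and kappa = 2 ln(ln n)
the Hannan-Quinn criterion, or with the likelihood-ratio test on
Lambda = GDEV_constrained - GDEV_unconstrained ~ chi2(1) under the null.
With one constraint, criterion kappa prefers M1 exactly when
Lambda > kappa, so AIC declares interaction most readily and BIC least
(for n >= 16, where 2 < 2 ln(ln n) < ln n).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy import stats

from .model_fit import (FittedModel, InfeasibleConstraintError,
                        fit_constrained, fit_unconstrained)

CRITERIA = ("AIC", "HQ", "BIC")


def kappa_for(criterion: str, n: int) -> float:
    """Penalty-per-parameter for a named criterion at sample size n."""
    criterion = criterion.upper()
    if criterion == "AIC":
        return 2.0
    if criterion == "BIC":
        return math.log(n)
    if criterion == "HQ":
        return 2.0 * math.log(math.log(n))
    raise ValueError(f"unknown criterion {criterion!r}")


def gaic(model: FittedModel, kappa: float) -> float:
    """Generalized AIC, ``GDEV + kappa * df``."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return model.gdev + kappa * model.df


def likelihood_ratio_test(m1: FittedModel, m2: FittedModel):
    """LRT of the constrained model m2 against the unconstrained m1.

    Returns ``(statistic, p_value)`` with the statistic
    ``Lambda = GDEV2 - GDEV1`` floored at 0 (optimizer noise can make it
    marginally negative) and the p-value from the upper tail of
    chi-square with ``df1 - df2`` degrees of freedom.
    """
    df_diff = m1.df - m2.df
    if df_diff < 1:
        raise ValueError("m2 must be nested in m1 (df1 > df2)")
    stat = max(m2.gdev - m1.gdev, 0.0)
    p = float(stats.chi2.sf(stat, df_diff))
    return stat, p


@dataclass
class CriterionVerdict:
    criterion: str
    kappa: float
    gaic_unconstrained: float
    gaic_constrained: float
    preferred: str          # "unconstrained" | "constrained"
    verdict: str            # "interaction" | "no_interaction"


@dataclass
class SelectionReport:
    """Side-by-side comparison of M1 (free) and M2 (additive null)."""

    gdev_unconstrained: float
    gdev_constrained: float | None
    delta_gdev: float | None
    df_diff: int | None
    criteria: list = field(default_factory=list)
    lrt_stat: float | None = None
    lrt_p: float | None = None
    n: int = 0
    infeasible: bool = False

    def verdict(self, criterion: str = "HQ") -> str:
        for cv in self.criteria:
            if cv.criterion == criterion.upper():
                return cv.verdict
        return "undefined"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "gdev_unconstrained": self.gdev_unconstrained,
            "gdev_constrained": self.gdev_constrained,
            "delta_gdev": self.delta_gdev,
            "df_diff": self.df_diff,
            "lrt_stat": self.lrt_stat,
            "lrt_p": self.lrt_p,
            "criteria": [vars(c) for c in self.criteria],
            "infeasible": self.infeasible,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_table(self) -> str:
        """Human-readable criterion table (3-decimal precision)."""
        lines = [f"{'criterion':<10}{'kappa':>8}{'GAIC_M1':>12}"
                 f"{'GAIC_M2':>12}  {'preferred':<14}{'verdict'}"]
        for c in self.criteria:
            lines.append(f"{c.criterion:<10}{c.kappa:>8.3f}"
                         f"{c.gaic_unconstrained:>12.3f}"
                         f"{c.gaic_constrained:>12.3f}  {c.preferred:<14}"
                         f"{c.verdict}")
        if self.lrt_stat is not None:
            lines.append(f"LRT: Lambda = {self.lrt_stat:.3f}, "
                         f"p = {self.lrt_p:.3f} (df = {self.df_diff})")
        return "\n".join(lines)


def select(data, criteria=CRITERIA) -> SelectionReport:
    """Fit both models and compare them by each requested criterion.

    A criterion declares interaction exactly when it prefers the
    unconstrained model, i.e. when ``delta GDEV > kappa``; at an exact tie
    the constrained (simpler) model wins.  If the constrained model is
    infeasible for the data the report carries the unconstrained fit only
    and undefined verdicts.
    """
    m1 = fit_unconstrained(data)
    try:
        m2 = fit_constrained(data)
    except InfeasibleConstraintError:
        return SelectionReport(gdev_unconstrained=m1.gdev,
                               gdev_constrained=None, delta_gdev=None,
                               df_diff=None, n=m1.n, infeasible=True)
    return compare(m1, m2, criteria)


def compare(m1: FittedModel, m2: FittedModel,
            criteria=CRITERIA) -> SelectionReport:
    """Build a :class:`SelectionReport` from two already-fitted models."""
    stat, p = likelihood_ratio_test(m1, m2)
    report = SelectionReport(
        gdev_unconstrained=m1.gdev, gdev_constrained=m2.gdev,
        delta_gdev=m2.gdev - m1.gdev, df_diff=m1.df - m2.df,
        lrt_stat=stat, lrt_p=p, n=m1.n)
    for name in criteria:
        kappa = kappa_for(name, m1.n)
        g1 = gaic(m1, kappa)
        g2 = gaic(m2, kappa)
        preferred = "unconstrained" if g1 < g2 else "constrained"
        report.criteria.append(CriterionVerdict(
            criterion=name.upper(), kappa=kappa,
            gaic_unconstrained=g1, gaic_constrained=g2, preferred=preferred,
            verdict="interaction" if preferred == "unconstrained"
            else "no_interaction"))
    return report
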