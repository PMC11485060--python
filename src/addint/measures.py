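"""Additive-interaction measures and delta-method confidence intervals.

Given the combined-level logistic coefficients ``theta = (t1, t2, t3)``
(log odds ratios of the a-only, b-only and jointly exposed cells against
the unexposed cell), the three classical measures of departure from
risk-difference additivity are

* ``RERI = e^t3 - e^t1 - e^t2 + 1`` — relative excess risk due to
  interaction; 0 under additivity.  Identical to the interaction
  contrast IC when the baseline risk ratio is 1.
* ``AP = RERI / e^t3`` — proportion of the joint-exposure effect
  attributable to interaction; 0 under additivity.
* ``S = (e^t3 - 1) / (e^t1 + e^t2 - 2)`` — synergy index; 1 under
  additivity, undefined when the denominator is non-positive.

Confidence intervals use the delta method: a normal interval for RERI and
AP, and a log-normal interval for S (the interval is built on log S and
exponentiated back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_fit import FittedModel

NULL_VALUES = {"RERI": 0.0, "AP": 0.0, "S": 1.0, "IC": 0.0}

_S_DENOM_TOL = 1e-12


def reri(theta) -> float:
    """Relative excess risk due to interaction, ``e^t3 - e^t1 - e^t2 + 1``."""
    t1, t2, t3 = theta
    return float(math.exp(t3) - math.exp(t1) - math.exp(t2) + 1.0)


#: The interaction-contrast estimator coincides with RERI on the odds-ratio
#: scale (reference risk ratio is 1).
interaction_contrast = reri


def ap(theta) -> float:
    """Attributable proportion due to interaction, ``RERI / e^t3``."""
    t1, t2, t3 = theta
    return reri(theta) / math.exp(t3)


def synergy_index(theta) -> float:
    """Synergy index ``(e^t3 - 1) / (e^t1 + e^t2 - 2)``.

    Returns ``nan`` when the denominator is non-positive (both exposures
    protective or null), in which case the index is undefined rather than
    erroneous.
    """
    t1, t2, t3 = theta
    denom = math.exp(t1) + math.exp(t2) - 2.0
    if denom <= _S_DENOM_TOL:
        return float("nan")
    return (math.exp(t3) - 1.0) / denom


_MEASURES = {"RERI": reri, "AP": ap, "S": synergy_index, "IC": reri}


@dataclass
class MeasureEstimate:
    """A point estimate of an interaction measure with its interval.

    ``verdict`` is ``no_interaction`` when the closed interval
    ``[lower, upper]`` contains the measure's null value (0 for RERI/AP/IC,
    1 for S), ``interaction`` otherwise, and ``undefined`` when the measure
    or its interval cannot be formed (e.g. non-positive S denominator).
    """

    measure: str
    point: float
    lower: float | None = None
    upper: float | None = None
    level: float = 0.95
    method: str = "delta"
    null_value: float = 0.0
    verdict: str = "undefined"
    diagnostics: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {"measure": self.measure, "point": self.point,
                "lower": self.lower, "upper": self.upper,
                "level": self.level, "method": self.method,
                "verdict": self.verdict}


def classify_interaction(estimate: MeasureEstimate) -> str:
    """Apply the null-value containment rule to an interval estimate.

    Containment is closed: a bound exactly at the null value counts as
    containing it (no interaction).
    """
    if estimate.verdict == "undefined" and (estimate.lower is None
                                            or estimate.upper is None):
        return "undefined"
    if not (np.isfinite(estimate.lower) and np.isfinite(estimate.upper)):
        return "undefined"
    inside = estimate.lower <= estimate.null_value <= estimate.upper
    return "no_interaction" if inside else "interaction"


def measure_gradient(measure: str, theta) -> np.ndarray:
    """Gradient of the measure (log S for ``S``) in (t1, t2, t3).

    Used by the delta method; RERI and AP gradients are of the measure
    itself, while for S the gradient of log S is returned because the
    interval is log-normal.
    """
    t1, t2, t3 = theta
    e1, e2, e3 = math.exp(t1), math.exp(t2), math.exp(t3)
    if measure in ("RERI", "IC"):
        return np.array([-e1, -e2, e3])
    if measure == "AP":
        return np.array([-e1 / e3, -e2 / e3, (e1 + e2 - 1.0) / e3])
    if measure == "S":
        denom = e1 + e2 - 2.0
        if denom <= _S_DENOM_TOL or e3 <= 1.0 + _S_DENOM_TOL:
            raise ValueError("log S gradient undefined for this theta")
        return np.array([-e1 / denom, -e2 / denom, e3 / (e3 - 1.0)])
    raise ValueError(f"unknown measure {measure!r}")


def delta_ci(model: FittedModel, measure: str, level: float = 0.95
             ) -> MeasureEstimate:
    """Delta-method confidence interval for RERI, AP or S from a fitted
    unconstrained model.

    The measure's variance is ``g' Sigma g`` with ``g`` the gradient in
    (t1, t2, t3) and ``Sigma`` the corresponding covariance block. RERI and
    AP get symmetric normal intervals; S gets a log-normal interval
    (normal on log S, exponentiated back), which requires S > 0.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if model.constrained:
        raise ValueError("delta_ci requires an unconstrained fit; the "
                         "constrained model fixes the measure at its null")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")

    theta = model.theta
    point = _MEASURES[measure](theta)
    est = MeasureEstimate(measure=measure, point=point, level=level,
                          method="delta", null_value=NULL_VALUES[measure])
    if not np.isfinite(point):
        est.diagnostics["reason"] = "measure undefined at the estimate"
        return est
    if measure == "S" and point <= 0.0:
        # log-normal interval needs S > 0
        est.diagnostics["reason"] = "synergy index non-positive; log-normal " \
                                    "interval undefined"
        return est

    z = stats.norm.ppf(0.5 + level / 2.0)
    sigma = model.theta_cov
    g = measure_gradient(measure, theta)
    var = float(g @ sigma @ g)
    se = math.sqrt(max(var, 0.0))
    if measure == "S":
        log_lo = math.log(point) - z * se
        log_hi = math.log(point) + z * se
        est.lower, est.upper = math.exp(log_lo), math.exp(log_hi)
    else:
        est.lower, est.upper = point - z * se, point + z * se
    est.diagnostics["se"] = se
    est.verdict = classify_interaction(est)
    return est
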