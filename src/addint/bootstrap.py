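"""Outcome-stratified bootstrap intervals for the interaction measures.

Case-control designs fix the numbers of cases and controls, so resampling
is done with replacement *within* each outcome stratum: every bootstrap
sample has exactly the original number of cases and of controls.  For
confounder-free data the resample of the 2x4 table is drawn directly as a
pair of multinomials (one per stratum), which is distributionally identical
to resampling rows and lets each replicate be refitted by the closed-form
saturated estimator.  Intervals are percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CorrectedCountTable, CountTable, ExposureDataset, \
    ZeroCellError
from .measures import (NULL_VALUES, MeasureEstimate, classify_interaction,
                       ap, reri, synergy_index)
from .model_fit import fit_unconstrained, saturated_from_counts

_MEASURE_FUNCS = {"RERI": reri, "AP": ap, "S": synergy_index}


def _point_theta(data):
    """Full-data theta, via the closed-form saturated fit when possible."""
    if isinstance(data, (CountTable, CorrectedCountTable)):
        return saturated_from_counts(data).theta
    if isinstance(data, ExposureDataset) and data.confounders is None:
        return saturated_from_counts(data.to_counts()).theta
    return fit_unconstrained(data).theta


@dataclass
class BootstrapSpec:
    """Settings for a stratified bootstrap run.

    ``zero_cell_policy`` controls resamples that empty a table cell:
    ``"correct"`` (default) adds the 0.5 continuity correction to all 8
    cells of that resample only; ``"drop"`` discards the resample (the
    percentile denominator shrinks accordingly; resamples are not topped
    up).  Either way the affected count is reported in the diagnostics.
    """

    replicates: int = 300
    level: float = 0.95
    seed: int | None = None
    zero_cell_policy: str = "correct"

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.zero_cell_policy not in ("correct", "drop"):
            raise ValueError("zero_cell_policy must be 'correct' or 'drop'")


def stratified_resample(data: ExposureDataset, seed) -> ExposureDataset:
    """One bootstrap resample drawn within cases and within controls.

    ``seed`` may be an integer or a ``numpy.random.Generator``; stratum
    sizes are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(data.outcome == 1)
    control_idx = np.flatnonzero(data.outcome == 0)
    if case_idx.size == 0 or control_idx.size == 0:
        raise ValueError("both outcome strata must be non-empty")
    take = np.concatenate([rng.choice(case_idx, size=case_idx.size),
                           rng.choice(control_idx, size=control_idx.size)])
    return ExposureDataset(
        outcome=data.outcome[take],
        exposure_level=data.exposure_level[take],
        confounders=None if data.confounders is None
        else data.confounders[take],
        confounder_names=data.confounder_names,
    )


def _resample_thetas_counts(table, replicates: int, rng,
                            policy: str):
    """Vectorized count-level resampling; returns (thetas, n_degenerate).

    ``thetas`` is a (replicates, 3) array; with the ``drop`` policy rows
    from degenerate resamples are all-nan.
    """
    cases, controls = table.as_arrays()
    n1, n0 = cases.sum(), controls.sum()
    A = rng.multinomial(int(n1), cases / n1, size=replicates).astype(float)
    B = rng.multinomial(int(n0), controls / n0, size=replicates).astype(float)
    degenerate = ((A == 0) | (B == 0)).any(axis=1)
    n_deg = int(degenerate.sum())
    if n_deg:
        if policy == "correct":
            A[degenerate] += 0.5
            B[degenerate] += 0.5
        else:                       # drop
            A[degenerate] = np.nan
            B[degenerate] = np.nan
    logodds = np.log(A) - np.log(B)
    thetas = logodds[:, 1:] - logodds[:, [0]]
    return thetas, n_deg


def _measure_values(thetas: np.ndarray):
    """RERI/AP/S per resample from a (R, 3) array of theta draws."""
    e = np.exp(thetas)
    reri_v = e[:, 2] - e[:, 0] - e[:, 1] + 1.0
    ap_v = reri_v / e[:, 2]
    denom = e[:, 0] + e[:, 1] - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s_v = np.where(denom > 1e-12, (e[:, 2] - 1.0) / denom, np.nan)
    return {"RERI": reri_v, "AP": ap_v, "S": s_v}


def bootstrap_theta_samples(data, spec: BootstrapSpec):
    """Bootstrap draws of (theta1, theta2, theta3), one row per resample.

    Confounder-free data uses the fast count-level path; data with
    confounders falls back to row resampling with a full refit per
    replicate.  Returns ``(thetas, diagnostics)``.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(data, (CountTable, CorrectedCountTable)) or (
            isinstance(data, ExposureDataset) and data.confounders is None):
        table = (data if isinstance(data, (CountTable, CorrectedCountTable))
                 else data.to_counts())
        thetas, n_deg = _resample_thetas_counts(table, spec.replicates, rng,
                                                spec.zero_cell_policy)
        n_unusable = n_deg if spec.zero_cell_policy == "drop" else 0
    else:
        rows = []
        n_deg = 0
        for _ in range(spec.replicates):
            sample = stratified_resample(data, rng)
            try:
                rows.append(fit_unconstrained(sample).theta)
            except Exception:
                n_deg += 1
                rows.append(np.full(3, np.nan))
        thetas = np.vstack(rows)
        n_unusable = n_deg
    if n_unusable > spec.replicates / 2:
        raise RuntimeError(f"{n_unusable}/{spec.replicates} bootstrap "
                           "resamples were unusable; the table is too sparse "
                           "for a bootstrap interval")
    diag = {"replicates": spec.replicates, "degenerate": n_deg,
            "policy": spec.zero_cell_policy}
    return thetas, diag


def _percentile_estimate(values: np.ndarray, measure: str, point: float,
                         spec: BootstrapSpec, diag: dict) -> MeasureEstimate:
    valid = values[np.isfinite(values)]
    n_undef = int(values.size - valid.size)
    est = MeasureEstimate(measure=measure, point=point, level=spec.level,
                          method="bootstrap",
                          null_value=NULL_VALUES[measure],
                          diagnostics={**diag, "undefined": n_undef})
    if valid.size < max(2, values.size // 2):
        est.diagnostics["reason"] = "too few valid resamples"
        return est
    alpha = 1.0 - spec.level
    est.lower, est.upper = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
    est.verdict = classify_interaction(est)
    return est


def bootstrap_ci(data, measure: str, spec: BootstrapSpec) -> MeasureEstimate:
    """Stratified-bootstrap percentile interval for RERI, AP or S.

    The point estimate is taken from the full-data fit; the interval from
    the percentiles of the measure over ``spec.replicates`` resamples.
    Resamples where the measure is undefined (non-positive S denominator)
    are excluded from the percentile computation and counted in the
    diagnostics.
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}")
    try:
        point = _MEASURE_FUNCS[measure](_point_theta(data))
    except ZeroCellError:
        if spec.zero_cell_policy != "correct" \
                or not isinstance(data, CountTable):
            raise
        point = _MEASURE_FUNCS[measure](
            saturated_from_counts(data.corrected()).theta)
    thetas, diag = bootstrap_theta_samples(data, spec)
    values = _measure_values(thetas)[measure]
    return _percentile_estimate(values, measure, point, spec, diag)


def bootstrap_all(data, spec: BootstrapSpec) -> dict:
    """RERI, AP and S intervals from one shared resample stream.

    Using a single stream makes the three verdicts directly comparable:
    whenever S is defined in every resample the three percentile intervals
    are transformations of the same empirical distribution.
    """
    theta_hat = _point_theta(data)
    thetas, diag = bootstrap_theta_samples(data, spec)
    values = _measure_values(thetas)
    return {m: _percentile_estimate(values[m], m, _MEASURE_FUNCS[m](theta_hat),
                                    spec, diag)
            for m in ("RERI", "AP", "S")}
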