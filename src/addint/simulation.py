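"""Synthetic case-control data and the method-comparison experiment.

Data are generated from the four-cell logistic model

    Y ~ Bernoulli(p),   logit p = theta0 + theta1*I(a_only)
                                 + theta2*I(b_only) + theta3*I(both),

with the exposure cell of each subject drawn from a multinomial over the
four combined levels (equal probabilities by default) and theta the log of
the scenario odds ratios.  Seven standard scenarios span strong synergy
(S1) through exact additivity (S4: OR11 = OR10 + OR01 - 1) to strong
antagonism (S7); the baseline log-odds theta0 is 0, so roughly half of the
unexposed cell are cases.

:func:`run_experiment` generates many replicate datasets under a scenario
and records, for each detection method, the fraction of replicates in
which the method declares *no* additive interaction — the type-I-error
complement under S4 and the miss rate elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSpec, bootstrap_theta_samples, _measure_values
from .data import CountTable, ExposureDataset, ZeroCellError
from .measures import ap, delta_ci, reri, synergy_index
from .model_fit import (InfeasibleConstraintError, fit_constrained,
                        saturated_from_counts)
from .model_selection import compare

DELTA_METHODS = ("RERI_D", "AP_D", "S_D")
BOOT_METHODS = ("RERI_B", "AP_B", "S_B")
CRITERION_METHODS = ("AIC", "HQ", "BIC")
ALL_METHODS = CRITERION_METHODS + DELTA_METHODS + BOOT_METHODS


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario defined by the three cell odds ratios.

    The implied coefficients are ``theta = (log or10, log or01, log or11)``
    and the implied measures follow the scenario algebra
    ``RERI = OR11 - OR10 - OR01 + 1``, ``AP = RERI/OR11``,
    ``S = (OR11 - 1)/(OR10 + OR01 - 2)``.
    """

    name: str
    or10: float
    or01: float
    or11: float
    theta0: float = 0.0

    def __post_init__(self):
        if min(self.or10, self.or01, self.or11) <= 0:
            raise ValueError("odds ratios must be positive")

    @property
    def theta(self) -> np.ndarray:
        return np.log([self.or10, self.or01, self.or11])

    @property
    def reri(self) -> float:
        return self.or11 - self.or10 - self.or01 + 1.0

    @property
    def ap(self) -> float:
        return self.reri / self.or11

    @property
    def synergy_index(self) -> float:
        denom = self.or10 + self.or01 - 2.0
        return (self.or11 - 1.0) / denom if denom > 0 else float("nan")


#: The seven standard scenarios: OR10 = 4 and OR01 = 5 throughout, with
#: the joint odds ratio sweeping from strong synergy to strong antagonism.
SCENARIOS = {
    "S1": ScenarioSpec("S1", 4, 5, 20),
    "S2": ScenarioSpec("S2", 4, 5, 16),
    "S3": ScenarioSpec("S3", 4, 5, 12),
    "S4": ScenarioSpec("S4", 4, 5, 8),     # additive null: 8 = 4 + 5 - 1
    "S5": ScenarioSpec("S5", 4, 5, 6),
    "S6": ScenarioSpec("S6", 4, 5, 4),
    "S7": ScenarioSpec("S7", 4, 5, 2),
}

EQUAL_ALLOCATION = (0.25, 0.25, 0.25, 0.25)


def scenario_table(scenarios=None) -> pd.DataFrame:
    """The scenario grid with its implied measures, one row per scenario."""
    specs = [SCENARIOS[s] if isinstance(s, str) else s
             for s in (scenarios or SCENARIOS.values())]
    return pd.DataFrame([
        {"scenario": s.name, "or10": s.or10, "or01": s.or01, "or11": s.or11,
         "reri": s.reri, "ap": s.ap, "s": s.synergy_index}
        for s in specs])


def _cell_probs(spec: ScenarioSpec) -> np.ndarray:
    eta = spec.theta0 + np.concatenate(([0.0], spec.theta))
    return 1.0 / (1.0 + np.exp(-eta))


def generate_counts(spec: ScenarioSpec, n: int, rng,
                    allocation=EQUAL_ALLOCATION) -> CountTable:
    """Draw one replicate directly as a 2x4 count table."""
    alloc = np.asarray(allocation, dtype=float)
    if not math.isclose(alloc.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("allocation probabilities must sum to 1")
    cell_n = rng.multinomial(n, alloc)
    p = _cell_probs(spec)
    cases = rng.binomial(cell_n, p)
    return CountTable(cases=tuple(int(c) for c in cases),
                      controls=tuple(int(c) for c in cell_n - cases))


def generate_dataset(spec: ScenarioSpec, n: int, seed,
                     allocation=EQUAL_ALLOCATION) -> ExposureDataset:
    """Generate one individual-level dataset under the scenario model.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Exposure
    levels are multinomial with the given allocation (equal cell
    probabilities by default); outcomes are Bernoulli at the cell's
    fitted probability.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    alloc = np.asarray(allocation, dtype=float)
    if not math.isclose(alloc.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("allocation probabilities must sum to 1")
    levels = rng.choice(4, size=n, p=alloc).astype(np.int8)
    p = _cell_probs(spec)
    outcome = (rng.random(n) < p[levels]).astype(np.int8)
    return ExposureDataset(outcome=outcome, exposure_level=levels)


@dataclass
class ExperimentResult:
    """No-interaction fractions per method over many simulated replicates.

    ``fractions[m]`` is the share of *valid* replicates in which method
    ``m`` declared no additive interaction; ``failures[m]`` counts
    replicates excluded from that method's denominator (fit failure or
    undefined measure), so the denominator is
    ``replicates - failures[m]``.
    """

    scenario: str
    n: int
    replicates: int
    seed: int | None
    fractions: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row = {"scenario": self.scenario, "n": self.n,
               "replicates": self.replicates, **self.fractions}
        return pd.DataFrame([row])


def _delta_verdicts(model, level):
    out = {}
    for name, measure in zip(DELTA_METHODS, ("RERI", "AP", "S")):
        est = delta_ci(model, measure, level=level)
        out[name] = est.verdict
    return out


def run_experiment(spec: ScenarioSpec, n: int, replicates: int = 1000,
                   methods=ALL_METHODS, seed: int | None = None,
                   bootstrap_replicates: int = 300, level: float = 0.95,
                   allocation=EQUAL_ALLOCATION,
                   zero_cell_policy: str = "correct") -> ExperimentResult:
    """Monte-Carlo comparison of detection methods under one scenario.

    Per replicate: a dataset of size ``n`` is generated, the saturated and
    constrained models are fitted, and each requested method issues a
    verdict — information criteria by comparing the two fits, delta
    methods by the null-containment of their 95% intervals, bootstrap
    methods by percentile intervals over ``bootstrap_replicates``
    outcome-stratified resamples (one shared stream for the three
    measures).  Replicates where a method cannot produce a verdict are
    excluded from that method's denominator and counted in ``failures``.

    A master seed spawns one independent substream per replicate, so
    results do not depend on evaluation order.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    need_delta = any(m in DELTA_METHODS for m in methods)
    need_boot = any(m in BOOT_METHODS for m in methods)
    need_crit = any(m in CRITERION_METHODS for m in methods)

    no_int = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.spawn(replicates)

    for child in child_seeds:
        data_seed, boot_seed = child.spawn(2)
        rng = np.random.default_rng(data_seed)
        table = generate_counts(spec, n, rng, allocation)
        corrected = None
        try:
            m1 = saturated_from_counts(table)
        except ZeroCellError:
            corrected = table.corrected()
            if corrected.zero_cells():       # an exposure level is empty
                for m in methods:
                    failures[m] += 1
                continue
            m1 = saturated_from_counts(corrected)
        fit_input = corrected if corrected is not None else table

        if need_delta:
            for name, measure in zip(DELTA_METHODS, ("RERI", "AP", "S")):
                if name not in methods:
                    continue
                est = delta_ci(m1, measure, level=level)
                if est.verdict == "undefined":
                    failures[name] += 1
                elif est.verdict == "no_interaction":
                    no_int[name] += 1

        if need_crit:
            try:
                m2 = fit_constrained(fit_input)
                report = compare(m1, m2)
                for name in CRITERION_METHODS:
                    if name not in methods:
                        continue
                    if report.verdict(name) == "no_interaction":
                        no_int[name] += 1
            except (InfeasibleConstraintError, RuntimeError):
                for name in CRITERION_METHODS:
                    if name in methods:
                        failures[name] += 1

        if need_boot:
            bspec = BootstrapSpec(replicates=bootstrap_replicates,
                                  level=level,
                                  seed=np.random.default_rng(boot_seed),
                                  zero_cell_policy=zero_cell_policy)
            try:
                thetas, _ = bootstrap_theta_samples(fit_input, bspec)
                values = _measure_values(thetas)
            except RuntimeError:
                for name in BOOT_METHODS:
                    if name in methods:
                        failures[name] += 1
                values = None
            if values is not None:
                alpha = 1.0 - level
                point_theta = m1.theta
                points = {"RERI_B": reri(point_theta),
                          "AP_B": ap(point_theta),
                          "S_B": synergy_index(point_theta)}
                for name, key in zip(BOOT_METHODS, ("RERI", "AP", "S")):
                    if name not in methods:
                        continue
                    vals = values[key]
                    valid = vals[np.isfinite(vals)]
                    if valid.size < max(2, vals.size // 2):
                        failures[name] += 1
                        continue
                    lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
                    null = 1.0 if key == "S" else 0.0
                    if lo <= null <= hi:
                        no_int[name] += 1

    fractions = {}
    for m in methods:
        denom = replicates - failures[m]
        fractions[m] = no_int[m] / denom if denom > 0 else float("nan")
    return ExperimentResult(scenario=spec.name, n=n, replicates=replicates,
                            seed=seed, fractions=fractions,
                            failures=failures)


def experiment_table(scenarios, sizes, replicates: int = 1000,
                     methods=ALL_METHODS, seed: int | None = None,
                     **kwargs) -> pd.DataFrame:
    """Run a grid of scenarios x sample sizes; one row per combination."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for n in sizes:
        for name in scenarios:
            spec = SCENARIOS[name] if isinstance(name, str) else name
            res = run_experiment(spec, n, replicates=replicates,
                                 methods=methods, seed=ss.spawn(1)[0],
                                 **kwargs)
            rows.append({"n": n, "scenario": spec.name, **res.fractions})
    return pd.DataFrame(rows)
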