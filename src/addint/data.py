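"""Data containers for two-binary-factor interaction analysis.

Two equivalent representations are supported: individual-level records
(one row per subject, with an optional confounder matrix) and the 2x4
case/control count table that summarises a study without confounders.
The four combined exposure levels are always ordered

    0: neither    (A=0, B=0)  -- the reference level
    1: a_only     (A=1, B=0)
    2: b_only     (A=0, B=1)
    3: both       (A=1, B=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEVELS = ("neither", "a_only", "b_only", "both")
LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}


class DegenerateDataError(ValueError):
    """Raised when a dataset cannot support the saturated logistic model."""


class ZeroCellError(DegenerateDataError):
    """A case/control cell is empty; carries the offending cell indices."""

    def __init__(self, cells):
        self.cells = list(cells)
        names = ", ".join(f"{'cases' if r == 0 else 'controls'}/{LEVELS[c]}"
                          for r, c in self.cells)
        super().__init__(f"empty cell(s): {names}")


@dataclass(frozen=True)
class CountTable:
    """Case/control counts over the four combined exposure levels.

    ``cases[j]`` and ``controls[j]`` count subjects with outcome 1 and 0
    at combined level ``j`` (order: neither, a_only, b_only, both).
    """

    cases: tuple
    controls: tuple

    def __post_init__(self):
        cases = tuple(int(c) for c in self.cases)
        controls = tuple(int(c) for c in self.controls)
        if len(cases) != 4 or len(controls) != 4:
            raise ValueError("cases and controls must each have 4 cells")
        if any(c < 0 for c in cases + controls):
            raise ValueError("cell counts must be nonnegative")
        if sum(cases + controls) == 0:
            raise ValueError("table is empty")
        object.__setattr__(self, "cases", cases)
        object.__setattr__(self, "controls", controls)

    @property
    def n(self) -> int:
        return sum(self.cases) + sum(self.controls)

    def as_arrays(self):
        """Return (cases, controls) as float arrays of length 4."""
        return (np.asarray(self.cases, dtype=float),
                np.asarray(self.controls, dtype=float))

    def zero_cells(self):
        """Indices (row, level) of empty cells; row 0 = cases."""
        out = []
        for j, c in enumerate(self.cases):
            if c == 0:
                out.append((0, j))
        for j, c in enumerate(self.controls):
            if c == 0:
                out.append((1, j))
        return out

    def corrected(self, amount: float = 0.5) -> "CorrectedCountTable":
        """Haldane-Anscombe continuity correction: add ``amount`` to all 8 cells.

        Returns a float-valued table; the correction is explicit and opt-in,
        nothing in the fitting code applies it silently.
        """
        return CorrectedCountTable(
            cases=tuple(c + amount for c in self.cases),
            controls=tuple(c + amount for c in self.controls),
        )

    def to_dataset(self) -> "ExposureDataset":
        """Expand to one row per subject (no confounders)."""
        levels = []
        outcome = []
        for j in range(4):
            levels.extend([j] * (self.cases[j] + self.controls[j]))
            outcome.extend([1] * self.cases[j] + [0] * self.controls[j])
        return ExposureDataset(outcome=np.asarray(outcome, dtype=np.int8),
                               exposure_level=np.asarray(levels, dtype=np.int8))


@dataclass(frozen=True)
class CorrectedCountTable:
    """A continuity-corrected table; cells are floats, used only for fitting."""

    cases: tuple
    controls: tuple

    @property
    def n(self) -> float:
        return float(sum(self.cases) + sum(self.controls))

    def as_arrays(self):
        return (np.asarray(self.cases, dtype=float),
                np.asarray(self.controls, dtype=float))

    def zero_cells(self):
        return [(r, j) for r, row in enumerate((self.cases, self.controls))
                for j, c in enumerate(row) if c <= 0]


@dataclass
class ExposureDataset:
    """Individual-level data: binary outcome, combined exposure level, and
    optional confounders.

    Parameters
    ----------
    outcome : array of 0/1, one per subject.
    exposure_level : array of level codes 0..3 (see :data:`LEVELS`).
    confounders : optional (n, p) float matrix of adjustment covariates.
    """

    outcome: np.ndarray
    exposure_level: np.ndarray
    confounders: np.ndarray | None = None
    confounder_names: tuple = field(default=())

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome)
        self.exposure_level = np.asarray(self.exposure_level)
        if self.outcome.ndim != 1 or self.exposure_level.ndim != 1:
            raise ValueError("outcome and exposure_level must be 1-d")
        if self.outcome.shape[0] != self.exposure_level.shape[0]:
            raise ValueError("outcome and exposure_level lengths differ")
        if self.outcome.shape[0] < 1:
            raise ValueError("dataset must contain at least one subject")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must be strictly binary (0/1)")
        if not np.isin(self.exposure_level, (0, 1, 2, 3)).all():
            raise ValueError("exposure_level codes must be in 0..3")
        if self.confounders is not None:
            self.confounders = np.atleast_2d(np.asarray(self.confounders,
                                                        dtype=float))
            if self.confounders.shape[0] != self.outcome.shape[0]:
                raise ValueError("confounder matrix must have n rows")
            if not self.confounder_names:
                self.confounder_names = tuple(
                    f"z{k}" for k in range(self.confounders.shape[1]))

    @property
    def n(self) -> int:
        return int(self.outcome.shape[0])

    @property
    def n_confounders(self) -> int:
        return 0 if self.confounders is None else self.confounders.shape[1]

    @classmethod
    def from_factors(cls, outcome, factor_a, factor_b, confounders=None,
                     confounder_names=()):
        """Build from separate binary exposures A and B."""
        a = np.asarray(factor_a)
        b = np.asarray(factor_b)
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("factors must be binary 0/1")
        level = a * (1 - b) * 1 + (1 - a) * b * 2 + a * b * 3
        return cls(outcome=np.asarray(outcome), exposure_level=level,
                   confounders=confounders, confounder_names=confounder_names)

    def factors(self):
        """Recover the (A, B) binary factors from the combined level."""
        lv = self.exposure_level
        a = ((lv == 1) | (lv == 3)).astype(np.int8)
        b = ((lv == 2) | (lv == 3)).astype(np.int8)
        return a, b

    def to_counts(self) -> CountTable:
        """Aggregate to a count table; confounders must be absent."""
        if self.confounders is not None:
            raise ValueError("cannot aggregate a dataset with confounders")
        cases = np.bincount(self.exposure_level[self.outcome == 1],
                            minlength=4)
        controls = np.bincount(self.exposure_level[self.outcome == 0],
                               minlength=4)
        return CountTable(cases=tuple(int(c) for c in cases),
                          controls=tuple(int(c) for c in controls))

    def design_matrix(self):
        """Full design matrix: intercept, three level dummies, confounders."""
        n = self.n
        X = np.zeros((n, 4 + self.n_confounders))
        X[:, 0] = 1.0
        for j in (1, 2, 3):
            X[self.exposure_level == j, j] = 1.0
        if self.confounders is not None:
            X[:, 4:] = self.confounders
        return X


#: Case-control counts of smoking (factor A) and alcohol use (factor B)
#: against oral cancer in 458 male veterans; the worked example used
#: throughout the documentation.
ORAL_CANCER = CountTable(cases=(3, 8, 6, 225), controls=(20, 18, 12, 166))
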