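"""Readers, writers and deterministic example-file generation.

Count tables travel as two-row delimited text (or JSON) with the four
level columns in the fixed order ``neither, a_only, b_only, both``;
individual-level data as delimited text with header columns
``outcome, factor_a, factor_b`` (binary 0/1) followed by any number of
confounder columns.  Comma is the default delimiter; tab is accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LEVELS, ORAL_CANCER, CountTable, ExposureDataset
from .simulation import SCENARIOS, generate_dataset


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty file: {path}")
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_counts(path) -> CountTable:
    """Read a 2x4 count table from CSV/TSV (rows cases, controls) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        try:
            return CountTable(cases=tuple(payload["cases"]),
                              controls=tuple(payload["controls"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"bad count JSON in {path}: {exc}") from exc

    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in LEVELS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing level column(s) {missing}; "
                         f"expected columns {list(LEVELS)}")
    label_col = df.columns[0] if df.columns[0] not in LEVELS else None
    if label_col is None and len(df) != 2:
        raise ParseError(f"{path}: expected exactly 2 unlabeled rows "
                         f"(cases, controls), found {len(df)}")
    rows = {}
    for i, row in df.iterrows():
        label = str(row[label_col]).strip().lower() if label_col else \
            ("cases", "controls")[i]
        rows[label] = row
    for needed in ("cases", "controls"):
        if needed not in rows:
            raise ParseError(f"{path}: missing row '{needed}'")

    def cells(row, label):
        out = []
        for c in LEVELS:
            v = row[c]
            if pd.isna(v) or (isinstance(v, float) and not v.is_integer()) \
                    or int(v) < 0:
                raise ParseError(f"{path}: bad count in row '{label}', "
                                 f"column '{c}': {v!r}")
            out.append(int(v))
        return tuple(out)

    return CountTable(cases=cells(rows["cases"], "cases"),
                      controls=cells(rows["controls"], "controls"))


def write_counts(table: CountTable, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "json" or path.suffix.lower() == ".json":
        path.write_text(json.dumps({"cases": list(table.cases),
                                    "controls": list(table.controls)},
                                   indent=2) + "\n")
        return
    lines = ["group," + ",".join(LEVELS),
             "cases," + ",".join(str(c) for c in table.cases),
             "controls," + ",".join(str(c) for c in table.controls)]
    path.write_text("\n".join(lines) + "\n")


def read_individuals(path) -> ExposureDataset:
    """Read individual-level data; extra columns become confounders."""
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("outcome", "factor_a", "factor_b"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
        bad = ~df[col].isin((0, 1))
        if bad.any():
            line = int(df.index[bad][0]) + 2     # +1 header, +1 zero-based
            raise ParseError(f"{path}: non-binary value in column '{col}' "
                             f"at line {line}: {df.loc[bad, col].iloc[0]!r}")
    extras = [c for c in df.columns
              if c not in ("outcome", "factor_a", "factor_b")]
    confounders = df[extras].to_numpy(dtype=float) if extras else None
    return ExposureDataset.from_factors(
        outcome=df["outcome"].to_numpy(dtype=np.int8),
        factor_a=df["factor_a"].to_numpy(dtype=np.int8),
        factor_b=df["factor_b"].to_numpy(dtype=np.int8),
        confounders=confounders, confounder_names=tuple(extras))


def write_individuals(data: ExposureDataset, path, sep: str = ",") -> None:
    a, b = data.factors()
    frame = pd.DataFrame({"outcome": data.outcome, "factor_a": a,
                          "factor_b": b})
    for k, name in enumerate(data.confounder_names):
        frame[name] = data.confounders[:, k]
    frame.to_csv(path, sep=sep, index=False)


FIXTURE_KINDS = ("oral_cancer", "additive_null") + tuple(SCENARIOS)


def make_fixture(kind: str, seed: int = 0, outdir=".") -> Path:
    """Write a deterministic example input file and return its path.

    ``oral_cancer`` writes the worked-example count table (byte-identical
    across calls); scenario names (S1..S7) write a simulated
    individual-level dataset of n = 600; ``additive_null`` writes a large
    (n = 10000) dataset generated under exact additivity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "oral_cancer":
        path = outdir / "oral_cancer_counts.csv"
        write_counts(ORAL_CANCER, path)
        return path
    if kind == "additive_null":
        path = outdir / f"additive_null_seed{seed}.csv"
        data = generate_dataset(SCENARIOS["S4"], 10_000, seed)
        write_individuals(data, path)
        return path
    if kind in SCENARIOS:
        path = outdir / f"{kind.lower()}_n600_seed{seed}.csv"
        data = generate_dataset(SCENARIOS[kind], 600, seed)
        write_individuals(data, path)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose from {FIXTURE_KINDS}")
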