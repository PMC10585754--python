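"""Reading fuzzy RDD datasets and writing fit reports.

File dialect: comma-separated, UTF-8, header row required, '.' decimal
separator.  Fuzzy variables occupy three adjacent columns per variable
(``y_lower, y_mode, y_upper`` and ``x_lower, x_mode, x_upper``); plain
``y, x`` columns are accepted and promoted to degenerate (crisp) triples.
An optional ``cluster_id`` column carries the sampling-cluster label.
Missing values are rejected — estimation is complete-case.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Union

import pandas as pd

from .estimator import SRDFit, RDDDataset
from .fuzzy import (
    FuzzyObservation,
    InvalidFuzzyNumberError,
    TriangularFuzzyNumber,
)

__all__ = [
    "SchemaError",
    "RowValidationError",
    "read_dataset",
    "write_dataset",
    "write_fit_report",
    "read_fit_report",
]

FUZZY_Y = ("y_lower", "y_mode", "y_upper")
FUZZY_X = ("x_lower", "x_mode", "x_upper")


class SchemaError(ValueError):
    """The input file lacks a recognised column layout."""


class RowValidationError(ValueError):
    """A data row violates the fuzzy-triple ordering invariant."""


def _triple(row: pd.Series, cols: tuple[str, str, str], row_num: int) -> TriangularFuzzyNumber:
    try:
        return TriangularFuzzyNumber(*(float(row[c]) for c in cols))
    except InvalidFuzzyNumberError as exc:
        raise RowValidationError(f"row {row_num}: {exc}") from exc


def read_dataset(
    path: Union[str, Path],
    cutoff: Union[float, TriangularFuzzyNumber],
    defuzzification: str = "centroid",
) -> RDDDataset:
    """Load a fuzzy RDD dataset from a CSV file.

    Accepts either the six fuzzy columns (plus optional ``cluster_id``) or
    crisp ``y, x`` columns, which are promoted to degenerate triples.
    Every triple is validated; a violated ordering raises
    ``RowValidationError`` naming the offending row (1-based, excluding the
    header).  Rows with missing values are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    fuzzy_layout = set(FUZZY_Y + FUZZY_X) <= cols
    crisp_layout = {"y", "x"} <= cols
    if not fuzzy_layout and not crisp_layout:
        missing = [c for c in FUZZY_Y + FUZZY_X if c not in cols]
        raise SchemaError(
            f"unrecognised column layout {sorted(cols)}; expected either "
            f"crisp columns ['y', 'x'] or fuzzy columns (missing: {missing})"
        )
    value_cols = list(FUZZY_Y + FUZZY_X) if fuzzy_layout else ["y", "x"]
    if df[value_cols].isna().any().any():
        bad = int(df[df[value_cols].isna().any(axis=1)].index[0]) + 1
        raise RowValidationError(
            f"row {bad}: missing value(s); complete cases are required"
        )
    has_cluster = "cluster_id" in cols
    observations = []
    for i, row in df.iterrows():
        row_num = int(i) + 1
        if fuzzy_layout:
            y_fz = _triple(row, FUZZY_Y, row_num)
            x_fz = _triple(row, FUZZY_X, row_num)
        else:
            y_fz = TriangularFuzzyNumber.crisp(float(row["y"]))
            x_fz = TriangularFuzzyNumber.crisp(float(row["x"]))
        cid = row["cluster_id"] if has_cluster else None
        observations.append(FuzzyObservation(y_fz, x_fz, cid))
    if not isinstance(cutoff, TriangularFuzzyNumber):
        cutoff = TriangularFuzzyNumber.crisp(float(cutoff))
    return RDDDataset(observations, cutoff, defuzzification)


def write_dataset(data: RDDDataset, path: Union[str, Path]) -> None:
    """Write a dataset back to the six-column fuzzy CSV layout."""
    rows = []
    ids = data.cluster_ids()
    for i, o in enumerate(data.observations):
        rec = {
            "y_lower": o.y_star.lower,
            "y_mode": o.y_star.mode,
            "y_upper": o.y_star.upper,
            "x_lower": o.x_star.lower,
            "x_mode": o.x_star.mode,
            "x_upper": o.x_star.upper,
        }
        if ids is not None:
            rec["cluster_id"] = ids[i]
        rows.append(rec)
    # %.17g guarantees exact float round-trips through the text format
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


_REPORT_FLOAT_KEYS = (
    "alpha",
    "beta",
    "gamma",
    "delta",
    "ace",
    "se_alpha",
    "se_beta",
    "se_gamma",
    "se_delta",
    "bandwidth_h",
    "cutoff",
)


def write_fit_report(fit: SRDFit, path: Union[str, Path]) -> None:
    """Emit a fit report: human-readable header plus machine key=value lines.

    The key=value section round-trips all numbers at 17 significant digits
    (full double precision).  Writing is atomic: the file appears only once
    complete, so a failure leaves no partial output behind.
    """
    a, b, g, d = fit.psi_hat
    sa, sb, sg, sd_ = fit.standard_errors
    human = (
        "# Sharp RDD fit (fuzzy observations defuzzified)\n"
        f"# parameterization={fit.parameterization}  "
        f"n_left={fit.n_left}  n_right={fit.n_right}  h={fit.bandwidth_h}\n"
        f"# ACE (delta) = {d:.6g}  [jump in outcome mean at the cutoff]\n"
    )
    pairs = {
        "parameterization": fit.parameterization,
        "alpha": a,
        "beta": b,
        "gamma": g,
        "delta": d,
        "ace": d,
        "se_alpha": sa,
        "se_beta": sb,
        "se_gamma": sg,
        "se_delta": sd_,
        "n_left": fit.n_left,
        "n_right": fit.n_right,
        "bandwidth_h": fit.bandwidth_h,
        "cutoff": fit.cutoff_value,
        "cov_type": fit.cov_type,
    }
    lines = [human]
    for k, v in pairs.items():
        lines.append(f"{k}={v:.17g}\n" if isinstance(v, float) else f"{k}={v}\n")
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.writelines(lines)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fit_report(path: Union[str, Path]) -> dict:
    """Parse the machine-readable key=value section of a fit report."""
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            if k in _REPORT_FLOAT_KEYS:
                out[k] = float(v)
            elif k in ("n_left", "n_right"):
                out[k] = int(v)
            else:
                out[k] = v
    return out
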