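"""Cross-parameter Pearson / RSQ matrices and their consistency audit.

When several kinetic reductions of the same plate are each expressed as
percent inhibition, their agreement across compounds at one concentration
(conventionally the highest tested, 10 uM) is summarised by the 6x6
Pearson product-moment correlation matrix and its elementwise square
(RSQ).  Published reports print both matrices rounded to two decimals —
which loses the guarantee that RSQ equals Pearson squared.  The
consistency audit flags cell pairs whose printed values cannot be
reconciled by rounding alone.

Internally everything is full precision; rounding happens only in report
output, so ``rsq_matrix`` is exactly the square of ``pearson_matrix``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inhibition import build_dose_response
from .plate_io import PlateLayout
from .reductions import ReductionResult

__all__ = [
    "PARAMETER_ORDER",
    "build_parameter_matrix",
    "pearson_matrix",
    "rsq_matrix",
    "round_report",
    "ConsistencyEntry",
    "consistency_report",
    "EXAMPLE_PRINTED_PEARSON",
    "EXAMPLE_PRINTED_RSQ",
]

#: Column order used in report matrices.
PARAMETER_ORDER: tuple[str, ...] = ("vmax", "peak", "slope", "mean", "t_half_max", "auc")


def build_parameter_matrix(
    results: Mapping[str, ReductionResult],
    layout: PlateLayout,
    conc: float = 1e-5,
    parameters: Sequence[str] = PARAMETER_ORDER,
) -> pd.DataFrame:
    """Compounds x parameters matrix of percent inhibition at one dose.

    Each cell is the mean percent inhibition over the replicates of that
    compound at concentration ``conc`` (matched to relative tolerance
    1e-6).  Compounds with no well at that concentration are omitted.
    """
    frames: dict[str, dict[str, float]] = {}
    for param in parameters:
        for compound, dr in build_dose_response(results, layout, param).items():
            vals = [
                pi for c, pi, _ in dr.points
                if np.isclose(c, conc, rtol=1e-6, atol=0.0) and np.isfinite(pi)
            ]
            if vals:
                frames.setdefault(compound, {})[param] = float(np.mean(vals))
    if not frames:
        raise ValueError(f"no sample wells found at concentration {conc} mol/L")
    return pd.DataFrame.from_dict(frames, orient="index")[list(parameters)]


def pearson_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r over compounds (rows), full precision.

    Diagonal is exactly 1.  A constant column has undefined correlation:
    its row and column are reported as ND (NaN).  Requires >= 3 rows.
    """
    if m.shape[0] < 3:
        raise ValueError(f"need >= 3 compounds for correlation, got {m.shape[0]}")
    x = m.to_numpy(dtype=float)
    k = x.shape[1]
    sd = x.std(axis=0)
    out = np.full((k, k), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(x[:, ok], rowvar=False)
        out[np.ix_(ok, ok)] = np.clip(np.atleast_2d(sub), -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=m.columns, columns=m.columns)


def rsq_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise square of the full-precision Pearson matrix."""
    return pearson_matrix(m) ** 2


def round_report(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Report-precision copy (printed tables use two decimals)."""
    return df.round(decimals)


@dataclass(frozen=True)
class ConsistencyEntry:
    pair: tuple[str, str]
    discrepancy: float   # |rsq - pearson^2|
    flagged: bool


def consistency_report(
    pearson: pd.DataFrame,
    rsq: pd.DataFrame,
    tol: float = 0.0075,
) -> list[ConsistencyEntry]:
    """Audit an (r, r^2) matrix pair for square-consistency.

    For every off-diagonal upper-triangle pair the discrepancy
    ``|rsq - pearson**2|`` is computed and flagged when it exceeds
    ``tol``.  The default tolerance of 0.0075 allows half an ulp (0.005)
    of the printed two-decimal r^2 plus half of the same allowance for
    the rounding of r itself — a deliberately strict audit that treats
    larger gaps as worth a second look even though rounding of a
    high-|r| cell can reach 0.005 + 0.01|r|; pass ``tol=0.015`` for the
    fully conservative bound that never flags a pair rounded from one
    full-precision source.  ND (NaN) cells are skipped.  Shape or label
    mismatch raises.
    """
    if pearson.shape != rsq.shape:
        raise ValueError(f"shape mismatch: {pearson.shape} vs {rsq.shape}")
    if list(pearson.columns) != list(rsq.columns) or list(pearson.index) != list(rsq.index):
        raise ValueError("pearson and rsq matrices must share row/column labels")
    out: list[ConsistencyEntry] = []
    cols = list(pearson.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            p = float(pearson.iloc[i, j])
            r2 = float(rsq.iloc[i, j])
            if np.isnan(p) or np.isnan(r2):
                continue
            d = abs(r2 - p * p)
            out.append(ConsistencyEntry((cols[i], cols[j]), d, d > tol))
    return out


def _report_df(rows: Sequence[Sequence[float]]) -> pd.DataFrame:
    return pd.DataFrame(
        np.array(rows, dtype=float), index=PARAMETER_ORDER, columns=PARAMETER_ORDER
    )


#: A published pair of 6x6 cross-parameter report matrices (percent
#: inhibition at the 10 uM dose, rounded to two decimals) used to
#: demonstrate the consistency audit: several printed RSQ cells do not
#: square-match the printed Pearson cells.
EXAMPLE_PRINTED_PEARSON = _report_df([
    [1.00, 0.95, 0.67, 0.97, 0.45, 0.54],
    [0.95, 1.00, 0.63, 0.97, 0.36, 0.54],
    [0.67, 0.63, 1.00, 0.63, -0.01, 0.81],
    [0.97, 0.97, 0.63, 1.00, 0.39, 0.54],
    [0.45, 0.36, -0.01, 0.39, 1.00, -0.01],
    [0.54, 0.54, 0.81, 0.54, -0.01, 1.00],
])

EXAMPLE_PRINTED_RSQ = _report_df([
    [1.00, 0.89, 0.45, 0.94, 0.20, 0.30],
    [0.89, 1.00, 0.40, 0.94, 0.13, 0.30],
    [0.45, 0.40, 1.00, 0.40, 0.00, 0.65],
    [0.94, 0.94, 0.40, 1.00, 0.15, 0.29],
    [0.20, 0.13, 0.00, 0.15, 1.00, 0.00],
    [0.30, 0.30, 0.65, 0.29, 0.00, 1.00],
])
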