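"""Kinetic data reductions for microplate time courses.

Six reductions summarise each well's curve inside the reduction limits
[t_min, t_max], mirroring standard plate-reader kinetic analysis:

* **Vmax rate** — a creeping iteration fits a least-squares line
  ``y = A x + B`` to every run of ``vmax_points`` contiguous readings; the
  steepest positive *or negative* slope (maximal |A|, signed, earliest
  window on ties) is reported in milli-OD/min, together with the start
  time of the winning window.
* **slope** — the least-squares slope over *all* readings in the window
  (identical to Vmax rate when ``vmax_points`` equals the run length).
* **AUC** — the curve is treated as a series of trapezoids with vertices
  at successive data points and their x-axis feet; areas are summed
  (OD·min, to the y = 0 baseline).
* **peak** — maximum OD in the window.
* **mean** — arithmetic mean OD in the window.
* **time to half-max** — the peak OD is halved and the earliest time the
  curve crosses that level is returned, linearly interpolated between the
  bracketing samples; ND when every reading already exceeds the target.

A seventh quantity, the **lag (induction) time**, is estimated by
intersecting the steepest-window tangent with a baseline line fitted to
the first three in-window readings; for a curve with no induction phase
the two lines coincide and the lag is 0, and the result is ND when the
curve never accelerates (Vmax <= 0) or the intersection falls beyond
t_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .curves import ND, KineticCurve, is_nd
from .plate_io import PlateLayout, ReductionSettings

__all__ = [
    "ReductionResult",
    "write_reductions",
    "read_reductions",
    "vmax_rate",
    "slope",
    "auc",
    "peak",
    "mean_od",
    "time_to_half_max",
    "lag_time",
    "reduce_curve",
    "reduce_plate",
]

#: ReductionResult attribute for each parameter name used in reports.
PARAMETER_FIELDS: Mapping[str, str] = {
    "vmax": "vmax_mOD_per_min",
    "peak": "peak_OD",
    "slope": "slope_mOD_per_min",
    "mean": "mean_OD",
    "t_half_max": "t_half_max_min",
    "auc": "auc_OD_min",
}


@dataclass
class ReductionResult:
    """All kinetic reductions of one well under one settings object."""

    well_id: str
    vmax_mOD_per_min: float
    time_to_vmax: float          # start time of the steepest window, min
    slope_mOD_per_min: float
    auc_OD_min: float
    peak_OD: float
    mean_OD: float
    t_half_max_min: float        # ND when never crossed
    lag_min: float               # ND when not detected
    settings: ReductionSettings


def _in_window(curve: KineticCurve, settings: ReductionSettings, min_points: int, op: str):
    w = curve.window(settings.t_min, settings.t_max)
    if len(w.times) < min_points:
        raise ValueError(
            f"{op}: well {curve.well_id} has {len(w.times)} readings in "
            f"[{settings.t_min}, {settings.t_max}] min, needs >= {min_points}"
        )
    return w.times, w.od


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on t (closed form)."""
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def _window_slopes(t: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Slopes of the LS line over every run of k consecutive points.

    Closed form via sliding sums: A = (k*Sty - St*Sy) / (k*Stt - St^2).
    """
    n = len(t)
    c = lambda v: np.concatenate(([0.0], np.cumsum(v)))
    st, sy = c(t), c(y)
    stt, sty = c(t * t), c(t * y)
    i = np.arange(n - k + 1)
    St = st[i + k] - st[i]
    Sy = sy[i + k] - sy[i]
    Stt = stt[i + k] - stt[i]
    Sty = sty[i + k] - sty[i]
    return (k * Sty - St * Sy) / (k * Stt - St * St)


def vmax_rate(
    curve: KineticCurve, settings: ReductionSettings | None = None
) -> tuple[float, float]:
    """Steepest windowed slope (creeping iteration).

    Returns ``(rate_mOD_per_min, window_start_time_min)``: the signed
    slope of maximal absolute value among least-squares fits to every run
    of ``settings.vmax_points`` contiguous in-window readings, ties broken
    by the earliest window.
    """
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, settings.vmax_points, "vmax_rate")
    slopes = _window_slopes(t, y, settings.vmax_points)
    i = int(np.argmax(np.abs(slopes)))  # argmax returns the first maximum
    return float(slopes[i]) * 1000.0, float(t[i])


def slope(curve: KineticCurve, settings: ReductionSettings | None = None) -> float:
    """Least-squares slope over all in-window readings, mOD/min."""
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, 2, "slope")
    return _ls_slope(t, y) * 1000.0


def auc(curve: KineticCurve, settings: ReductionSettings | None = None) -> float:
    """Trapezoid-sum area to the y = 0 baseline, OD*min."""
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, 2, "auc")
    return float(np.trapezoid(y, t))


def peak(curve: KineticCurve, settings: ReductionSettings | None = None) -> float:
    """Maximum OD inside the reduction limits."""
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, 1, "peak")
    return float(np.max(y))


def mean_od(curve: KineticCurve, settings: ReductionSettings | None = None) -> float:
    """Arithmetic mean OD inside the reduction limits."""
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, 1, "mean_od")
    return float(np.mean(y))


def time_to_half_max(
    curve: KineticCurve, settings: ReductionSettings | None = None
) -> float:
    """Earliest time the curve crosses half of its in-window peak.

    Linear interpolation between the bracketing samples; an exact hit on a
    sample returns that sample's time.  ND when every in-window reading
    exceeds the target (the curve starts above half-max and never returns).
    """
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, 2, "time_to_half_max")
    target = np.max(y) / 2.0
    d = y - target
    if np.all(d > 0):
        return ND
    if d[0] == 0.0:
        return float(t[0])
    for i in range(len(d) - 1):
        if d[i + 1] == 0.0:
            return float(t[i + 1])
        if d[i] * d[i + 1] < 0:
            return float(t[i] + (t[i + 1] - t[i]) * (-d[i]) / (d[i + 1] - d[i]))
    # d[0] < 0 and no sign change: curve stays below target except at the
    # peak sample itself, which the loop catches; defensive fallback.
    return ND


def lag_time(
    curve: KineticCurve, settings: ReductionSettings | None = None
) -> float:
    """Induction time by tangent-baseline intersection.

    The steepest-window tangent (from :func:`vmax_rate`) is intersected
    with a least-squares baseline line through the first three in-window
    readings.  A curve with no induction phase has (near-)coincident
    lines and a lag of 0.  Returns ND when the curve never accelerates
    (Vmax <= 0) or the intersection exceeds ``t_max``; estimates below 0
    are clipped to 0.
    """
    settings = settings or ReductionSettings()
    t, y = _in_window(curve, settings, settings.vmax_points + 1, "lag_time")
    if np.ptp(y) == 0.0:
        return ND  # flat trace: no oxidation, no induction point
    slopes = _window_slopes(t, y, settings.vmax_points)
    i = int(np.argmax(np.abs(slopes)))
    v = float(slopes[i])  # OD/min
    if v <= 0:
        return ND
    k = settings.vmax_points
    # LS lines pass through their window centroid.
    tw, yw = t[i : i + k], y[i : i + k]
    t_star, y_star = float(tw.mean()), float(yw.mean())
    nb = min(3, len(t))
    tb, yb = t[:nb], y[:nb]
    t_b, y_b = float(tb.mean()), float(yb.mean())
    v_b = _ls_slope(tb, yb) if nb >= 2 else 0.0
    dv = v - v_b
    if dv <= 1e-9 * max(abs(v), 1e-12):
        # Tangent parallel to (or shallower than) the baseline: the curve is
        # steepest from the start, i.e. no induction phase.
        return 0.0
    lag = ((y_b - v_b * t_b) - (y_star - v * t_star)) / dv
    if lag > settings.t_max:
        return ND
    return max(lag, 0.0)


def reduce_curve(
    curve: KineticCurve, settings: ReductionSettings | None = None
) -> ReductionResult:
    """All reductions of one curve (see module docstring for definitions)."""
    settings = settings or ReductionSettings()
    vmax, t_vmax = vmax_rate(curve, settings)
    return ReductionResult(
        well_id=curve.well_id,
        vmax_mOD_per_min=vmax,
        time_to_vmax=t_vmax,
        slope_mOD_per_min=slope(curve, settings),
        auc_OD_min=auc(curve, settings),
        peak_OD=peak(curve, settings),
        mean_OD=mean_od(curve, settings),
        t_half_max_min=time_to_half_max(curve, settings),
        lag_min=lag_time(curve, settings),
        settings=settings,
    )


def reduce_plate(
    curves: Mapping[str, KineticCurve],
    layout: PlateLayout,
    settings: ReductionSettings | None = None,
) -> dict[str, ReductionResult]:
    """Reduce every non-blank well of a (blank-corrected) plate.

    Per-well failures are re-raised with the well id attached.  Results
    are keyed by well and independent of iteration order.
    """
    settings = settings or ReductionSettings()
    roles = {e.well_id: e.role for e in layout.entries}
    out: dict[str, ReductionResult] = {}
    for well in sorted(curves, key=lambda w: (w[0], int(w[1:]))):
        if roles.get(well) == "blank":
            continue
        try:
            out[well] = reduce_curve(curves[well], settings)
        except ValueError as exc:
            raise ValueError(f"well {well}: {exc}") from exc
    return out


_CSV_COLUMNS = (
    "well", "vmax_mOD_per_min", "time_to_vmax_min", "slope_mOD_per_min",
    "auc_OD_min", "peak_OD", "mean_OD", "t_half_max_min", "lag_min",
)


def write_reductions(results: Mapping[str, ReductionResult], path) -> None:
    """One CSV row per well; ND values written as the string 'ND'."""
    import pandas as pd
    from .curves import format_nd

    rows = []
    for well in sorted(results, key=lambda w: (w[0], int(w[1:]))):
        r = results[well]
        rows.append({
            "well": r.well_id,
            "vmax_mOD_per_min": r.vmax_mOD_per_min,
            "time_to_vmax_min": r.time_to_vmax,
            "slope_mOD_per_min": r.slope_mOD_per_min,
            "auc_OD_min": r.auc_OD_min,
            "peak_OD": r.peak_OD,
            "mean_OD": r.mean_OD,
            "t_half_max_min": format_nd(r.t_half_max_min, "{:.10g}"),
            "lag_min": format_nd(r.lag_min, "{:.10g}"),
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_reductions(path, settings: ReductionSettings | None = None) -> dict[str, ReductionResult]:
    """Inverse of :func:`write_reductions` (settings are not serialised)."""
    import pandas as pd
    from .curves import parse_nd

    df = pd.read_csv(path, dtype=str)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing reduction columns {sorted(missing)}")
    settings = settings or ReductionSettings()
    out = {}
    for _, row in df.iterrows():
        well = str(row["well"]).upper()
        out[well] = ReductionResult(
            well_id=well,
            vmax_mOD_per_min=parse_nd(row["vmax_mOD_per_min"]),
            time_to_vmax=parse_nd(row["time_to_vmax_min"]),
            slope_mOD_per_min=parse_nd(row["slope_mOD_per_min"]),
            auc_OD_min=parse_nd(row["auc_OD_min"]),
            peak_OD=parse_nd(row["peak_OD"]),
            mean_OD=parse_nd(row["mean_OD"]),
            t_half_max_min=parse_nd(row["t_half_max_min"]),
            lag_min=parse_nd(row["lag_min"]),
            settings=settings,
        )
    return out
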