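"""Plate-read and layout I/O, blank correction, reduction settings.

Two delimited-text dialects are supported for kinetic reads:

* ``long`` — columns ``well,time_min,od``, one row per reading;
* ``wide`` — first column time (minutes), remaining columns one per well.

Comma and tab separators are autodetected.  Layouts are CSVs with columns
``well,compound,conc_molar,role,solvent``; roles are control / blank /
sample.  Blank correction subtracts the per-timepoint mean of the blank
wells from every other well and drops the blanks — running it a second
time under the subtract policy therefore fails (no blanks remain), which
guards against double correction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .curves import ND, KineticCurve, WELL_RE, is_nd

__all__ = [
    "LayoutEntry",
    "PlateLayout",
    "ReductionSettings",
    "read_plate",
    "write_plate",
    "read_layout",
    "write_layout",
    "blank_correct",
]

Role = Literal["control", "blank", "sample"]
_ROLES = ("control", "blank", "sample")


@dataclass(frozen=True)
class LayoutEntry:
    well_id: str
    compound: str
    final_conc: float | None  # mol/L in well; required for samples
    role: str
    solvent: str = ""

    def __post_init__(self):
        object.__setattr__(self, "well_id", self.well_id.strip().upper())


@dataclass
class PlateLayout:
    """Map of well -> (compound, in-well concentration, role)."""

    entries: list[LayoutEntry]

    def __post_init__(self):
        seen: set[str] = set()
        for e in self.entries:
            if not WELL_RE.match(e.well_id):
                raise ValueError(f"invalid well coordinate in layout: {e.well_id!r}")
            if e.well_id in seen:
                raise ValueError(f"duplicate well in layout: {e.well_id}")
            seen.add(e.well_id)
            if e.role not in _ROLES:
                raise ValueError(
                    f"well {e.well_id}: role must be one of {_ROLES}, got {e.role!r}"
                )
            if e.role == "sample":
                if e.final_conc is None or is_nd(e.final_conc):
                    raise ValueError(f"sample well {e.well_id} has no concentration")
                if e.final_conc <= 0:
                    raise ValueError(
                        f"sample well {e.well_id}: concentration must be > 0, "
                        f"got {e.final_conc}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def by_well(self) -> dict[str, LayoutEntry]:
        return {e.well_id: e for e in self.entries}

    def wells(self, role: str | None = None) -> list[str]:
        return [e.well_id for e in self.entries if role is None or e.role == role]

    def require_controls(self) -> None:
        if not self.wells("control"):
            raise ValueError("layout has no control wells; inhibition analysis needs >= 1")


@dataclass(frozen=True)
class ReductionSettings:
    """Window and options shared by all kinetic reductions.

    ``t_min``/``t_max`` are the reduction limits in minutes: every
    reduction sees only readings inside the closed window.  ``vmax_points``
    is the number of contiguous readings per creeping-iteration segment.
    """

    t_min: float = 0.0
    t_max: float = 70.0
    vmax_points: int = 5
    blank_policy: str = "subtract_mean_blank"

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise ValueError(f"require t_min < t_max, got [{self.t_min}, {self.t_max}]")
        if self.vmax_points < 2:
            raise ValueError(f"vmax_points must be >= 2, got {self.vmax_points}")
        if self.blank_policy not in ("subtract_mean_blank", "none"):
            raise ValueError(f"unknown blank_policy {self.blank_policy!r}")


def _read_table(path) -> pd.DataFrame:
    """Delimited read with comma/tab autodetection and strict columns."""
    text = Path(path).read_text()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        return pd.read_csv(io.StringIO(text), sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc


def read_plate(path, dialect: str = "long") -> dict[str, KineticCurve]:
    """Read kinetic curves from a long- or wide-format delimited file.

    Raises ValueError naming the offending well / line for duplicate
    (well, time) pairs, non-numeric readings and non-increasing times.
    """
    df = _read_table(path)
    if dialect == "long":
        required = {"well", "time_min", "od"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: long dialect needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        for col in ("time_min", "od"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise ValueError(
                    f"{path}: non-numeric {col} at line {int(bad[0]) + 2}"
                )
            df[col] = vals
        dup = df.duplicated(subset=["well", "time_min"])
        if dup.any():
            line = int(df.index[dup][0]) + 2
            raise ValueError(f"{path}: duplicate (well, time) pair at line {line}")
        curves = {}
        for well, grp in df.groupby("well", sort=False):
            t = grp["time_min"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{path}: well {well}: times not strictly increasing")
            curves[str(well).upper()] = KineticCurve(str(well), t, grp["od"].to_numpy(float))
        return curves
    if dialect == "wide":
        tcol = df.columns[0]
        t = pd.to_numeric(df[tcol], errors="coerce")
        if t.isna().any():
            line = int(df.index[t.isna()][0]) + 2
            raise ValueError(f"{path}: non-numeric time at line {line}")
        tv = t.to_numpy(float)
        if not np.all(np.diff(tv) > 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        curves = {}
        for col in df.columns[1:]:
            od = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[od.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric OD for well {col} at line {int(bad[0]) + 2}"
                )
            curves[str(col).upper()] = KineticCurve(str(col), tv, od.to_numpy(float))
        return curves
    raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def write_plate(curves: Mapping[str, KineticCurve] | Iterable[KineticCurve],
                path, dialect: str = "long") -> None:
    """Write curves to delimited text (inverse of :func:`read_plate`)."""
    if isinstance(curves, Mapping):
        curves = list(curves.values())
    else:
        curves = list(curves)
    if dialect == "long":
        frames = [
            pd.DataFrame({"well": c.well_id, "time_min": c.times, "od": c.od})
            for c in curves
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    if dialect == "wide":
        t0 = curves[0].times
        for c in curves:
            if len(c.times) != len(t0) or not np.allclose(c.times, t0):
                raise ValueError(
                    f"wide dialect needs a shared time grid; well {c.well_id} differs"
                )
        out = pd.DataFrame({"time_min": t0})
        for c in curves:
            out[c.well_id] = c.od
        out.to_csv(path, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def read_layout(path) -> PlateLayout:
    df = _read_table(path)
    required = {"well", "compound", "conc_molar", "role"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: layout needs columns {sorted(required)}, found {list(df.columns)}"
        )
    entries = []
    for _, row in df.iterrows():
        conc = row["conc_molar"]
        conc = None if pd.isna(conc) else float(conc)
        entries.append(
            LayoutEntry(
                str(row["well"]),
                str(row["compound"]),
                conc,
                str(row["role"]).strip().lower(),
                "" if "solvent" not in df.columns or pd.isna(row.get("solvent"))
                else str(row["solvent"]),
            )
        )
    return PlateLayout(entries)


def write_layout(layout: PlateLayout, path) -> None:
    pd.DataFrame(
        {
            "well": [e.well_id for e in layout.entries],
            "compound": [e.compound for e in layout.entries],
            "conc_molar": [e.final_conc for e in layout.entries],
            "role": [e.role for e in layout.entries],
            "solvent": [e.solvent for e in layout.entries],
        }
    ).to_csv(path, index=False)


def blank_correct(
    curves: Mapping[str, KineticCurve],
    layout: PlateLayout,
    settings: ReductionSettings | None = None,
) -> dict[str, KineticCurve]:
    """Subtract the mean blank trace and drop blank wells.

    Under policy ``subtract_mean_blank`` the per-timepoint mean OD of all
    blank wells is subtracted from every non-blank well.  Negative
    corrected ODs are retained (clipping would bias slopes).  Policy
    ``none`` returns the curves unchanged.
    """
    settings = settings or ReductionSettings()
    if settings.blank_policy == "none":
        return dict(curves)
    roles = {e.well_id: e.role for e in layout.entries}
    blanks = [w for w, c in curves.items() if roles.get(w) == "blank"]
    if not blanks:
        raise ValueError(
            "blank_policy=subtract_mean_blank but no blank wells present "
            "(already corrected?)"
        )
    ref = curves[blanks[0]]
    for w in blanks[1:]:
        if len(curves[w]) != len(ref) or not np.allclose(curves[w].times, ref.times):
            raise ValueError("blank wells are not on a common time grid")
    mean_blank = np.mean([curves[w].od for w in blanks], axis=0)
    out = {}
    for w, c in curves.items():
        if roles.get(w) == "blank":
            continue
        if len(c) != len(ref) or not np.allclose(c.times, ref.times):
            raise ValueError(f"well {w} is not on the blank wells' time grid")
        out[w] = KineticCurve(c.well_id, c.times.copy(), c.od - mean_blank, c.temperature_c)
    return out
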