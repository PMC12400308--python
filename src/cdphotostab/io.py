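"""CSV interchange for every series type.

All files are plain UTF-8 CSV with mandatory headers and '.' decimals;
concentrations are always molar in files (display scaling such as x10^3
belongs to report rendering).  Schemas:

=============  ==========================================================
kind           columns
=============  ==========================================================
timecourse     ph, cd_type, cd_conc_M, time_min, response
kobs           ph, cd_type, cd_conc_M, kobs_per_min
quench         ph, cd_type, cd_conc_M, fluorescence  (cd_conc_M = 0 -> F0)
job            mole_fraction, delta_a
conduct        cd_conc_M, conductivity_uScm
calib          cd_type, nominal_conc_M, response [, replicate]
=============  ==========================================================

Readers validate cell by cell and report failures as ``file:line`` (line 1
is the header), then construct the domain objects, so invariant violations
carry their provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinetics import TimeCourse
from .photophysics import QuenchingSeries
from .stoichiometry import ConductivitySeries, JobSeries
from .validation import CalibrationSeries

__all__ = ["SCHEMAS", "SchemaError", "read_series", "write_timecourses",
           "write_quench", "write_job", "write_conduct", "write_calib",
           "write_kobs"]

SCHEMAS: dict[str, tuple[str, ...]] = {
    "timecourse": ("ph", "cd_type", "cd_conc_M", "time_min", "response"),
    "kobs": ("ph", "cd_type", "cd_conc_M", "kobs_per_min"),
    "quench": ("ph", "cd_type", "cd_conc_M", "fluorescence"),
    "job": ("mole_fraction", "delta_a"),
    "conduct": ("cd_conc_M", "conductivity_uScm"),
    "calib": ("cd_type", "nominal_conc_M", "response"),
}

_NUMERIC_EXEMPT = {"cd_type"}


class SchemaError(ValueError):
    """A CSV file violating its schema, with file:line provenance."""


def _load(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise ValueError(f"unknown series kind {kind!r}; "
                         f"expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for "
                          f"kind {kind!r}")
    for col in SCHEMAS[kind]:
        if col in _NUMERIC_EXEMPT:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise SchemaError(
                f"{path}:{bad[0] + 2}: non-numeric value "
                f"{df.loc[bad[0], col]!r} in column {col!r}"
            )
        df[col] = coerced
    return df


def _check(cond: bool, path: Path, row: int, msg: str) -> None:
    if not cond:
        raise SchemaError(f"{path}:{row + 2}: {msg}")


def read_series(path: str | Path, kind: str):
    """Read and validate a series CSV, returning typed domain objects.

    Returns
    -------
    ``timecourse``
        list of :class:`TimeCourse`, one per (ph, cd_type, cd_conc_M) group.
    ``kobs``
        validated :class:`pandas.DataFrame` in schema order.
    ``quench``
        list of :class:`QuenchingSeries`, one per (ph, cd_type) group; the
        row with ``cd_conc_M == 0`` supplies F0.
    ``job`` / ``conduct``
        a single :class:`JobSeries` / :class:`ConductivitySeries`.
    ``calib``
        dict ``cd_type -> CalibrationSeries``.
    """
    path = Path(path)
    df = _load(path, kind)

    if kind == "timecourse":
        for i, row in df.iterrows():
            _check(row.time_min >= 0, path, i, f"negative time {row.time_min}")
            _check(row.response > 0, path, i,
                   f"non-positive response {row.response}")
        out = []
        for (ph, cd, conc), grp in df.groupby(["ph", "cd_type", "cd_conc_M"],
                                              sort=True):
            grp = grp.sort_values("time_min")
            out.append(TimeCourse(times=grp.time_min.to_numpy(),
                                  responses=grp.response.to_numpy(),
                                  ph=float(ph), cd_type=str(cd),
                                  cd_conc=float(conc)))
        return out

    if kind == "kobs":
        for i, row in df.iterrows():
            _check(row.kobs_per_min > 0, path, i,
                   f"non-positive kobs {row.kobs_per_min}")
            _check(row.cd_conc_M >= 0, path, i,
                   f"negative concentration {row.cd_conc_M}")
        return df[list(SCHEMAS["kobs"])].copy()

    if kind == "quench":
        out = []
        for (ph, cd), grp in df.groupby(["ph", "cd_type"], sort=True):
            zero = grp[grp.cd_conc_M == 0]
            _check(len(zero) == 1, path, int(grp.index[0]),
                   f"group (pH {ph}, {cd}) needs exactly one cd_conc_M = 0 "
                   "row for F0")
            f0 = float(zero.fluorescence.iloc[0])
            rest = grp[grp.cd_conc_M > 0].sort_values("cd_conc_M")
            out.append(QuenchingSeries(
                quencher_concs=rest.cd_conc_M.to_numpy(), f0=f0,
                f=rest.fluorescence.to_numpy(), ph=float(ph),
                cd_type=str(cd)))
        return out

    if kind == "job":
        df = df.sort_values("mole_fraction")
        return JobSeries(mole_fractions=df.mole_fraction.to_numpy(),
                         delta_a=df.delta_a.to_numpy())

    if kind == "conduct":
        df = df.sort_values("cd_conc_M")
        return ConductivitySeries(concs=df.cd_conc_M.to_numpy(),
                                  conductivity=df.conductivity_uScm.to_numpy())

    # calib
    out = {}
    has_rep = "replicate" in df.columns
    for cd, grp in df.groupby("cd_type", sort=True):
        out[str(cd)] = CalibrationSeries(
            nominal_concs=grp.nominal_conc_M.to_numpy(),
            responses=grp.response.to_numpy(), label=str(cd),
            replicate=grp.replicate.to_numpy() if has_rep else None)
    return out


# -- writers (round-trip partners of the readers) ---------------------------

def write_timecourses(courses: Iterable[TimeCourse], path: str | Path) -> None:
    rows = [
        {"ph": tc.ph, "cd_type": tc.cd_type, "cd_conc_M": tc.cd_conc,
         "time_min": t, "response": r}
        for tc in courses for t, r in zip(tc.times, tc.responses)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_kobs(df: pd.DataFrame, path: str | Path) -> None:
    df[list(SCHEMAS["kobs"])].to_csv(path, index=False)


def write_quench(series: Iterable[QuenchingSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        rows.append({"ph": s.ph, "cd_type": s.cd_type, "cd_conc_M": 0.0,
                     "fluorescence": s.f0})
        rows.extend({"ph": s.ph, "cd_type": s.cd_type, "cd_conc_M": q,
                     "fluorescence": f}
                    for q, f in zip(s.quencher_concs, s.f))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_job(series: JobSeries, path: str | Path) -> None:
    pd.DataFrame({"mole_fraction": series.mole_fractions,
                  "delta_a": series.delta_a}).to_csv(path, index=False)


def write_conduct(series: ConductivitySeries, path: str | Path) -> None:
    pd.DataFrame({"cd_conc_M": series.concs,
                  "conductivity_uScm": series.conductivity}
                 ).to_csv(path, index=False)


def write_calib(series_by_cd: dict[str, CalibrationSeries],
                path: str | Path) -> None:
    rows = []
    for cd, s in series_by_cd.items():
        rep = s.replicate if s.replicate is not None else np.zeros(
            s.nominal_concs.size, dtype=int)
        rows.extend({"cd_type": cd, "nominal_conc_M": x, "response": y,
                     "replicate": int(r)}
                    for x, y, r in zip(s.nominal_concs, s.responses, rep))
    pd.DataFrame(rows).to_csv(path, index=False)
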