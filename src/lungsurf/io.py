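"""CSV/JSON readers and writers for the pipeline's file interfaces.

All formats are plain UTF-8 text with mandatory headers:

* trace CSV:   ``time_s,gamma_mN_per_m,area_mm2[,volume_uL]``
* contour CSV: ``s_mm,r_mm,z_mm``
* records CSV: ``chemical_id,invitro_inhibitory,ghs_category,lc50_mg_per_L,signs``
  where ``signs`` packs observations as ``term@window;term@window``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lungsurf.adsa import DropProfile
from lungsurf.concordance import ChemicalRecord
from lungsurf.errors import SchemaError
from lungsurf.traces import SurfaceTensionTrace

TRACE_COLUMNS = ["time_s", "gamma_mN_per_m", "area_mm2"]
CONTOUR_COLUMNS = ["s_mm", "r_mm", "z_mm"]
RECORD_COLUMNS = ["chemical_id", "invitro_inhibitory", "ghs_category", "lc50_mg_per_L", "signs"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def write_trace_csv(trace: SurfaceTensionTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "gamma_mN_per_m": trace.surface_tension,
            "area_mm2": trace.surface_area,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_trace_csv(path: str | Path, frame_rate: float | None = None) -> SurfaceTensionTrace:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    for col in TRACE_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric or missing value in column {col!r}, row {bad[0] + 2}")
    t = df["time_s"].to_numpy(float)
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    return SurfaceTensionTrace(
        time=t,
        surface_tension=df["gamma_mN_per_m"].to_numpy(float),
        surface_area=df["area_mm2"].to_numpy(float),
        frame_rate=frame_rate,
        metadata={"source": str(path)},
    )


def write_contour_csv(profile: DropProfile, path: str | Path) -> None:
    pd.DataFrame({"s_mm": profile.s, "r_mm": profile.r, "z_mm": profile.z}).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_contour_csv(path: str | Path) -> DropProfile:
    df = pd.read_csv(path)
    _require_columns(df, CONTOUR_COLUMNS, path)
    return DropProfile(
        s=df["s_mm"].to_numpy(float),
        r=df["r_mm"].to_numpy(float),
        z=df["z_mm"].to_numpy(float),
        phi=np.zeros(len(df)),  # turning angle unknown for observed contours
    )


def fit_result_json(gamma: float, r0: float, residual: float, n_points: int) -> dict:
    return {
        "gamma_mN_per_m": gamma,
        "R0_mm": r0,
        "residual_mm": residual,
        "n_points": n_points,
    }


def _pack_signs(observations: list[tuple[str, str]]) -> str:
    return ";".join(f"{term}@{window}" for term, window in observations)


def _unpack_signs(cell: str, path, row: int) -> list[tuple[str, str]]:
    if not cell or pd.isna(cell):
        return []
    out = []
    for piece in str(cell).split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if "@" not in piece:
            raise SchemaError(f"{path}: row {row}, column 'signs': expected 'term@window', got {piece!r}")
        term, _, window = piece.rpartition("@")
        out.append((term.strip(), window.strip()))
    return out


def write_records_csv(records: list[ChemicalRecord], path: str | Path) -> None:
    rows = [
        {
            "chemical_id": r.chemical_id,
            "invitro_inhibitory": r.invitro_inhibitory,
            "ghs_category": r.ghs_category,
            "lc50_mg_per_L": r.lc50_mg_per_l if r.lc50_mg_per_l is not None else "",
            "signs": _pack_signs(r.observations),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_records_csv(path: str | Path) -> list[ChemicalRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RECORD_COLUMNS[:3] + ["signs"], path)
    if df.empty:
        raise SchemaError(f"{path}: no chemical records")
    records = []
    for i, row in df.iterrows():
        flag = row["invitro_inhibitory"].strip().lower()
        if flag not in _TRUE | _FALSE:
            raise SchemaError(
                f"{path}: row {i + 2}, column 'invitro_inhibitory': expected boolean, got {flag!r}"
            )
        lc50_cell = str(row.get("lc50_mg_per_L", "")).strip()
        records.append(
            ChemicalRecord(
                chemical_id=row["chemical_id"],
                invitro_inhibitory=flag in _TRUE,
                ghs_category=row["ghs_category"].strip(),
                lc50_mg_per_l=float(lc50_cell) if lc50_cell else None,
                observations=_unpack_signs(row["signs"], path, i + 2),
            )
        )
    return records


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
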