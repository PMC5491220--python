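"""Readers and writers for the pipeline's plain-text formats.

Formats are deliberately minimal and strict (comma-separated, dot
decimal): a long-format growth CSV, an 8x12 plate grid CSV paired with a
well-layout CSV, a per-animal metadata CSV, and a truth JSON for
simulated cohorts. Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bka import CurveRole, GrowthCurve
from .elisa import ElisaPlate, WellInfo, WellRole, well_to_index
from .synth import SimulatedCohort

_GROWTH_COLUMNS = ["sample_id", "role", "time_h", "od600"]
_LAYOUT_COLUMNS = ["well", "role", "sample_id", "replicate", "concentration", "paired_sample_id"]
_ROWS = "ABCDEFGH"


def write_growth_csv(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = [
        {"sample_id": c.sample_id, "role": c.role.value, "time_h": t, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od)
    ]
    pd.DataFrame(rows, columns=_GROWTH_COLUMNS).to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Load growth curves, grouped by (sample, role), times sorted ascending.

    Rejects missing columns, non-numeric or negative ODs, unknown roles
    and duplicate time points within a curve, naming the offending rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_h", "od600"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col} at rows {bad[:5]}")
        df[col] = vals
    neg = df.index[df["od600"] < 0].tolist()
    if neg:
        raise ValueError(f"{path}: negative od600 at rows {neg[:5]}")
    curves = []
    for (sid, role), grp in df.groupby(["sample_id", "role"], sort=True):
        if grp["time_h"].duplicated().any():
            raise ValueError(f"{path}: duplicate time points for sample {sid!r} ({role})")
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                sample_id=str(sid),
                role=CurveRole(role),
                times=tuple(grp["time_h"].astype(float)),
                od=tuple(grp["od600"].astype(float)),
            )
        )
    return curves


def write_plate_csv(plate: ElisaPlate, values_path: str | Path, layout_path: str | Path) -> None:
    grid = pd.DataFrame(
        plate.wells, index=list(_ROWS), columns=[str(i) for i in range(1, 13)]
    )
    grid.to_csv(values_path, index_label="row")
    rows = []
    for well, info in plate.layout.items():
        rows.append(
            {
                "well": well,
                "role": info.role.value,
                "sample_id": info.sample_id if info.sample_id is not None else "",
                "replicate": info.replicate if info.replicate is not None else "",
                "concentration": info.concentration if info.concentration is not None else "",
                "paired_sample_id": info.paired_sample_id if info.paired_sample_id is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(layout_path, index=False)


def read_plate_csv(values_path: str | Path, layout_path: str | Path) -> ElisaPlate:
    """Load one plate: an 8x12 grid CSV (rows A-H, columns 1-12) plus layout.

    The layout must reference only wells on the plate, each at most once;
    wells absent from the layout are ignored.
    """
    grid = pd.read_csv(values_path, index_col=0, float_precision="round_trip")
    if list(grid.index) != list(_ROWS) or list(grid.columns) != [str(i) for i in range(1, 13)]:
        raise ValueError(f"{values_path}: expected rows A-H and columns 1-12")
    wells = grid.to_numpy(dtype=float)
    lay = pd.read_csv(layout_path, dtype=str).fillna("")
    missing = {"well", "role"} - set(lay.columns)
    if missing:
        raise ValueError(f"{layout_path}: missing columns {sorted(missing)}")
    if lay["well"].duplicated().any():
        dupes = lay.loc[lay["well"].duplicated(), "well"].tolist()
        raise ValueError(f"{layout_path}: duplicate well assignment {dupes}")
    layout: dict[str, WellInfo] = {}
    for _, row in lay.iterrows():
        well = str(row["well"]).strip()
        well_to_index(well)  # raises on malformed / out-of-plate wells
        layout[well] = WellInfo(
            role=WellRole(row["role"]),
            sample_id=row.get("sample_id") or None,
            replicate=int(row["replicate"]) if row.get("replicate") not in ("", None) else None,
            concentration=float(row["concentration"]) if row.get("concentration") not in ("", None) else None,
            paired_sample_id=row.get("paired_sample_id") or None,
        )
    return ElisaPlate(wells=wells, layout=layout)


def write_metadata_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "population", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, cls=_TruthEncoder))


def write_cohort_bundle(sim: SimulatedCohort, outdir: str | Path) -> dict[str, list[str]]:
    """Write a simulated cohort as the pipeline's on-disk input bundle.

    Produces ``growth.csv``, ``plate<N>_values.csv`` / ``plate<N>_layout.csv``
    per plate, ``metadata.csv`` and ``truth.json``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_growth_csv(sim.curves, outdir / "growth.csv")
    plate_paths = []
    for i, plate in enumerate(sim.plates, start=1):
        vp, lp = outdir / f"plate{i}_values.csv", outdir / f"plate{i}_layout.csv"
        write_plate_csv(plate, vp, lp)
        plate_paths.append([str(vp), str(lp)])
    # nab_a450 is derived from the plates downstream; metadata carries the
    # per-animal facts that come from elsewhere (ranges, sex, the kit IgM).
    write_metadata_csv(sim.cohort.drop(columns=["nab_a450"]), outdir / "metadata.csv")
    write_truth_json(sim.truth, outdir / "truth.json")
    return {
        "growth": [str(outdir / "growth.csv")],
        "plates": plate_paths,
        "metadata": [str(outdir / "metadata.csv")],
        "truth": [str(outdir / "truth.json")],
    }
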