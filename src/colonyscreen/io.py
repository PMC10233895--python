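"""Tab-separated file formats for every pipeline stage.

All tables are TSV with an optional block of '#'-prefixed metadata lines
(tool version, parameters) before the header, so each stage's output is
self-describing and can be fed back in standalone. Gene sets are plain
text, one identifier per line. Simulation ground truth and overlap
reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DuplicateRecordError, FormatError
from .growth_curves import GrowthCurve
from .synthetic_screen import PlateLayout, SimulationTruth

CURVE_COLUMNS = ["plate_id", "row", "col", "time_h", "value"]
LAYOUT_COLUMNS = ["plate_id", "row", "col", "strain_id", "is_control", "condition", "replicate"]


def _write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# colonyscreen {__version__}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty table")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def write_curves(curves: dict, path, params: dict | None = None) -> None:
    """Long-format curve table: plate_id, row, col, time_h, value."""
    frames = []
    for pid in sorted(curves):
        for c in curves[pid]:
            frames.append(
                pd.DataFrame(
                    {
                        "plate_id": pid,
                        "row": c.row,
                        "col": c.col,
                        "time_h": c.times,
                        "value": c.values,
                    }
                )
            )
    _write_tsv(pd.concat(frames, ignore_index=True), path, params)


def read_curves(path) -> dict:
    """Read a long-format curve TSV back into per-plate GrowthCurve lists.

    Validates the schema (missing columns and non-numeric fields are
    format/parse errors naming the offender; duplicated
    (plate, row, col, time) rows are rejected) and sorts each colony's
    series by time.
    """
    df = _read_tsv(path, CURVE_COLUMNS)
    for col in ("row", "col", "time_h", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric value in column '{col}' near line {line}"
            )
        df[col] = numeric
    dup = df.duplicated(subset=["plate_id", "row", "col", "time_h"])
    if dup.any():
        raise DuplicateRecordError(
            f"{path}: duplicate (plate, row, col, time) record near line "
            f"{int(dup.idxmax()) + 2}"
        )
    curves: dict[str, list[GrowthCurve]] = {}
    for (pid, row, col), g in df.groupby(["plate_id", "row", "col"], sort=True):
        g = g.sort_values("time_h")
        curves.setdefault(str(pid), []).append(
            GrowthCurve(
                plate_id=str(pid),
                row=int(row),
                col=int(col),
                times=g["time_h"].to_numpy(),
                values=g["value"].to_numpy(),
            )
        )
    return curves


def write_layouts(layouts: dict, path, params: dict | None = None) -> None:
    rows = []
    for pid in sorted(layouts):
        lay = layouts[pid]
        for r, c in lay.positions():
            sid = lay.strain_ids[r, c]
            rows.append(
                (pid, r, c, "" if sid is None else sid,
                 bool(lay.is_control[r, c]), lay.condition, lay.replicate)
            )
    _write_tsv(pd.DataFrame(rows, columns=LAYOUT_COLUMNS), path, params)


def read_layouts(path) -> dict:
    df = _read_tsv(path, LAYOUT_COLUMNS)
    layouts: dict[str, PlateLayout] = {}
    for pid, g in df.groupby("plate_id", sort=True):
        rows = int(g["row"].max()) + 1
        cols = int(g["col"].max()) + 1
        strains = np.full((rows, cols), None, dtype=object)
        is_control = np.zeros((rows, cols), dtype=bool)
        sid = g["strain_id"].astype(object).where(g["strain_id"].notna(), None)
        strains[g["row"], g["col"]] = sid.to_numpy(dtype=object)
        is_control[g["row"], g["col"]] = g["is_control"].to_numpy(dtype=bool)
        layouts[str(pid)] = PlateLayout(
            plate_id=str(pid),
            rows=rows,
            cols=cols,
            strain_ids=strains,
            is_control=is_control,
            condition=str(g["condition"].iloc[0]),
            replicate=int(g["replicate"].iloc[0]),
        )
    return layouts


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "effects": truth.effects,
        "bias_surface": np.asarray(truth.bias_surface).tolist(),
        "corrupted": [list(t) for t in truth.corrupted],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    return SimulationTruth(
        effects=payload["effects"],
        bias_surface=np.asarray(payload["bias_surface"]),
        corrupted=[tuple(t) for t in payload["corrupted"]],
        seed=payload["seed"],
    )


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Generic stage table (doubling times, normalized phenotypes, calls)."""
    _write_tsv(df, path, params)


def read_table(path, required: list[str]) -> pd.DataFrame:
    return _read_tsv(path, required)


def write_hit_list(strains, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{s}\n" for s in sorted(strains)))


def write_overlap_report(results, path) -> None:
    """Overlap results as JSON (one object per comparison)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps([r.as_dict() for r in results], indent=1)
    )


def load_config_file(path) -> dict:
    """YAML or JSON key-value config; format chosen by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
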