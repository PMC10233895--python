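"""Spatial normalization of doubling times against control colonies.

Colony arrays show smooth position-dependent growth differences (plate
edges, temperature and moisture gradients, pinning pressure). The screen
design interleaves reference control colonies at every fourth plate
position; interpolating their log2 doubling times across the plate gives,
for every position, the log2(D) a control would have had there. The
normalized phenotype is

    log2(D)_norm = log2(D) - surface(row, col)

so that a control colony is ~0 everywhere and an experimental colony
measures growth relative to the local control level.

The surface estimator is a Gaussian-kernel locally weighted linear fit
(LOESS-style, degree 1) to the control values, evaluated at every plate
position and clipped to the observed control value range. Local-linear
weighting reproduces tilted bias fields without the boundary shrinkage a
plain weighted mean suffers at plate edges, while the clip keeps the
surface inside the range the controls actually span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientControlsError, InvalidParameterError

MIN_CONTROLS = 4
DEFAULT_BANDWIDTH = 3.0  # grid units; 1.5x the control spacing


def fit_control_surface(
    control_positions,
    control_values,
    plate_shape: tuple[int, int],
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> np.ndarray:
    """Gaussian-kernel local-linear fit of control log2(D), per position.

    ``control_positions`` is a sequence of (row, col); non-finite control
    values are dropped from the fit. Requires at least 4 usable controls.
    The returned surface is clipped to [min, max] of the control values.
    """
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    rows, cols = plate_shape
    pos = np.asarray(control_positions, dtype=float).reshape(-1, 2)
    vals = np.asarray(control_values, dtype=float)
    if pos.shape[0] != vals.size:
        raise InvalidParameterError("control positions and values differ in length")
    keep = np.isfinite(vals)
    pos, vals = pos[keep], vals[keep]
    if vals.size < MIN_CONTROLS:
        raise InsufficientControlsError(
            f"need >= {MIN_CONTROLS} usable controls, got {vals.size}"
        )

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)  # (P, 2)
    dr = pos[None, :, 0] - grid[:, None, 0]  # (P, k)
    dc = pos[None, :, 1] - grid[:, None, 1]
    w = np.exp(-(dr * dr + dc * dc) / (2.0 * bandwidth * bandwidth))

    # weighted least squares y ~ 1 + dr + dc per evaluation point; the
    # intercept is the local-linear estimate at the point itself
    P = grid.shape[0]
    X = np.empty((P, 3, 3))
    X[:, 0, 0] = w.sum(axis=1)
    X[:, 0, 1] = X[:, 1, 0] = (w * dr).sum(axis=1)
    X[:, 0, 2] = X[:, 2, 0] = (w * dc).sum(axis=1)
    X[:, 1, 1] = (w * dr * dr).sum(axis=1)
    X[:, 1, 2] = X[:, 2, 1] = (w * dr * dc).sum(axis=1)
    X[:, 2, 2] = (w * dc * dc).sum(axis=1)
    b = np.empty((P, 3))
    b[:, 0] = w @ vals
    b[:, 1] = (w * dr) @ vals
    b[:, 2] = (w * dc) @ vals
    # ridge on the slope terms guards the solve when controls are sparse
    # or collinear near a corner; it does not bias the intercept for flat data
    X[:, 1, 1] += 1e-9
    X[:, 2, 2] += 1e-9
    beta = np.linalg.solve(X, b[:, :, None])[:, :, 0]
    surface = np.clip(beta[:, 0], vals.min(), vals.max())
    return surface.reshape(rows, cols)


def normalize_plate(phenotypes: pd.DataFrame, surface: np.ndarray) -> pd.DataFrame:
    """Subtract the control surface from each colony's log2(D).

    ``phenotypes`` needs columns row, col, log2D (others pass through).
    Adds control_surface and log2D_norm columns; colonies whose log2D is
    missing (QC-failed) propagate NaN.
    """
    rows, cols = surface.shape
    r = phenotypes["row"].to_numpy(dtype=int)
    c = phenotypes["col"].to_numpy(dtype=int)
    if r.size and (r.min() < 0 or r.max() >= rows or c.min() < 0 or c.max() >= cols):
        raise InvalidParameterError(
            f"colony positions exceed surface shape {surface.shape}"
        )
    out = phenotypes.copy()
    out["control_surface"] = surface[r, c]
    out["log2D_norm"] = out["log2D"] - out["control_surface"]
    return out


def normalize_screen(
    doubling: pd.DataFrame,
    layouts: dict,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> pd.DataFrame:
    """Per-plate surface fit + normalization for a whole screen.

    ``doubling`` holds the per-colony estimates of all plates (columns
    plate_id, row, col, log2D, qc_pass); ``layouts`` maps plate_id to its
    :class:`~colonyscreen.synthetic_screen.PlateLayout`. Returns the table
    with strain_id, is_control, condition, replicate, control_surface and
    log2D_norm attached.
    """
    pieces = []
    for pid, plate in doubling.groupby("plate_id", sort=True):
        layout = layouts[pid]
        plate = plate.copy()
        r = plate["row"].to_numpy(dtype=int)
        c = plate["col"].to_numpy(dtype=int)
        plate["strain_id"] = layout.strain_ids[r, c]
        plate["is_control"] = layout.is_control[r, c]
        plate["condition"] = layout.condition
        plate["replicate"] = layout.replicate

        ctrl = plate[plate["is_control"] & plate["qc_pass"]]
        surface = fit_control_surface(
            ctrl[["row", "col"]].to_numpy(),
            ctrl["log2D"].to_numpy(),
            (layout.rows, layout.cols),
            bandwidth,
        )
        pieces.append(normalize_plate(plate, surface))
    return pd.concat(pieces, ignore_index=True)
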