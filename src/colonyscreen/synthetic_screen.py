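"""Synthetic colony-array screens with known ground truth.

Emulates a 1536-format (32x48) chemical-genomic screen: each plate carries
1152 experimental gene-deletion colonies plus 384 reference (his3-like)
control colonies interleaved at every fourth position, grown under a
background medium and one or more stressor conditions with replication.

Colony growth follows a logistic model; a colony's doubling time is
composed, on the log2 scale, of a plate-wide baseline, a smooth spatial
bias surface shared by all plates, a per-strain per-condition effect
(zero for controls), and independent colony-to-colony noise:

    log2(D) = log2(baseline_D) + bias(row, col) + effect(strain, cond) + eps

Positive effects mean slower growth, i.e. sensitivity to the condition.
A small fraction of curves is replaced by high-variance noise around the
inoculum to emulate corrupted measurements that downstream QC must reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CapacityError, InvalidParameterError
from .growth_curves import GrowthCurve

CONTROL_STRAIN = "CONTROL"


@dataclass
class SimulationConfig:
    """Design and noise parameters of one synthetic screen.

    Defaults emulate the study conditions of a solid-medium phenomics
    screen: 32x48 plates, 384 interleaved controls, 3 replicates per
    condition, 20-minute imaging over 72 h, ~1e5 cells inoculated per
    colony, and a 0.3% rate of corrupted growth curves.
    """

    rows: int = 32
    cols: int = 48
    control_offset: tuple[int, int] = (0, 0)
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("background", "metal")
    sampling_interval: float = 1.0 / 3.0  # hours (20 min)
    duration: float = 72.0  # hours
    baseline_D: float = 2.5  # wild-type doubling time, hours
    K: float = 1e7  # carrying capacity, cells
    N0: float = 1e5  # inoculum, cells
    bias_amplitude: float = 0.2  # log2(D) units, peak scale of spatial bias
    noise_sd: float = 0.05  # log2(D) units, colony-to-colony noise
    effect_table: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    corruption_rate: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        if self.rows <= 0 or self.cols <= 0 or (self.rows * self.cols) % 4 != 0:
            raise InvalidParameterError("rows*cols must be positive and divisible by 4")
        if self.control_offset[0] not in (0, 1) or self.control_offset[1] not in (0, 1):
            raise InvalidParameterError("control_offset must be a (0|1, 0|1) parity pair")
        if self.sampling_interval <= 0:
            raise InvalidParameterError("sampling_interval must be > 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        if not (0 < self.N0 < self.K):
            raise InvalidParameterError("need 0 < N0 < K")
        if self.baseline_D <= 0:
            raise InvalidParameterError("baseline_D must be > 0")
        if not (0 <= self.corruption_rate < 1):
            raise InvalidParameterError("corruption_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if len(self.conditions) < 1:
            raise InvalidParameterError("at least one condition required")

    def times(self) -> np.ndarray:
        """Sampling grid in hours, inclusive of t=0."""
        n = int(math.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


@dataclass
class PlateLayout:
    """Strain placement and control mask for one plate."""

    plate_id: str
    rows: int
    cols: int
    strain_ids: np.ndarray  # (rows, cols) object array; None = empty position
    is_control: np.ndarray  # (rows, cols) bool
    condition: str
    replicate: int

    def positions(self):
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated screen."""

    effects: dict  # strain -> condition -> log2(D) effect
    bias_surface: np.ndarray  # (rows, cols), log2(D) units, shared by all plates
    corrupted: list  # (plate_id, row, col) of corrupted curves
    seed: int


def logistic_curve(N0: float, K: float, r: float, times) -> np.ndarray:
    """Logistic population size N(t) = K*N0*e^{rt} / (K + N0*(e^{rt}-1)).

    ``r`` is the exponential-phase rate per hour; the exponential-phase
    doubling time is D = ln(2)/r.
    """
    if N0 <= 0 or K <= 0:
        raise InvalidParameterError("N0 and K must be positive")
    if K < N0:
        raise InvalidParameterError("K must be >= N0")
    if r < 0:
        raise InvalidParameterError("r must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    # computed as N0*K / (N0 + (K-N0)*e^{-rt}) to avoid overflow at large rt
    return N0 * K / (N0 + (K - N0) * np.exp(-r * t))


def _bias_surface(rows: int, cols: int, amplitude: float) -> np.ndarray:
    """Smooth spatial bias: linear gradient plus one low-frequency cosine.

    Both components are smooth on the scale of the control spacing so a
    kernel interpolation of the controls can capture them. The cosine runs
    along the column axis with a full period across the plate and zero
    slope at the plate edges, keeping edge extrapolation mild.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    gradient = (rr / max(rows - 1, 1)) + (cc / max(cols - 1, 1)) - 1.0  # in [-1, 1]
    wave = np.cos(2.0 * np.pi * cc / max(cols, 1))
    return amplitude * 0.5 * (gradient + wave)


def make_layout(
    config: SimulationConfig,
    strain_ids: Sequence[str],
    condition: str = "background",
    replicate: int = 1,
    plate_id: str | None = None,
) -> PlateLayout:
    """Place strains row-major on the plate, controls at every fourth position.

    The control mask is the interleaved sub-grid whose (row mod 2, col mod 2)
    parity equals ``config.control_offset``; on a 32x48 plate that is 384
    positions, leaving 1152 for experimental strains.
    """
    config.validate()
    rows, cols = config.rows, config.cols
    n_control = rows * cols // 4
    capacity = rows * cols - n_control
    if len(strain_ids) > capacity:
        raise CapacityError(
            f"{len(strain_ids)} strains exceed plate capacity {capacity}"
        )
    pr, pc = config.control_offset
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    is_control = (rr % 2 == pr) & (cc % 2 == pc)
    strains = np.full((rows, cols), None, dtype=object)
    strains[is_control] = CONTROL_STRAIN
    it = iter(strain_ids)
    for r in range(rows):
        for c in range(cols):
            if is_control[r, c]:
                continue
            strains[r, c] = next(it, None)
    if plate_id is None:
        plate_id = f"{condition}_rep{replicate}"
    return PlateLayout(
        plate_id=plate_id,
        rows=rows,
        cols=cols,
        strain_ids=strains,
        is_control=is_control,
        condition=condition,
        replicate=replicate,
    )


def simulate_screen(config: SimulationConfig, strain_ids: Sequence[str]):
    """Simulate one full screen: every condition x replicate as one plate.

    Returns ``(curves, layouts, truth)`` where ``curves`` maps plate_id to a
    list of :class:`GrowthCurve` and ``layouts`` maps plate_id to its
    :class:`PlateLayout`. Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.times()
    bias = _bias_surface(config.rows, config.cols, config.bias_amplitude)
    base_log2D = math.log2(config.baseline_D)

    effects = {s: dict(conds) for s, conds in config.effect_table.items()}
    curves: dict[str, list[GrowthCurve]] = {}
    layouts: dict[str, PlateLayout] = {}
    corrupted: list[tuple[str, int, int]] = []

    for condition in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            layout = make_layout(config, strain_ids, condition, rep)
            pid = layout.plate_id
            layouts[pid] = layout

            eff = np.zeros((config.rows, config.cols))
            for r in range(config.rows):
                for c in range(config.cols):
                    sid = layout.strain_ids[r, c]
                    if sid is None or layout.is_control[r, c]:
                        continue
                    eff[r, c] = effects.get(sid, {}).get(condition, 0.0)

            noise = (
                rng.normal(0.0, config.noise_sd, size=(config.rows, config.cols))
                if config.noise_sd > 0
                else np.zeros((config.rows, config.cols))
            )
            log2D = base_log2D + bias + eff + noise
            rates = math.log(2) / np.exp2(log2D)
            corrupt_mask = rng.random((config.rows, config.cols)) < config.corruption_rate

            # all colonies of the plate in one logistic evaluation
            flat_rates = rates.reshape(-1, 1)
            N0, K = config.N0, config.K
            values_mat = N0 * K / (N0 + (K - N0) * np.exp(-flat_rates * times[None, :]))

            plate_curves: list[GrowthCurve] = []
            for r in range(config.rows):
                for c in range(config.cols):
                    if layout.strain_ids[r, c] is None:
                        continue
                    if corrupt_mask[r, c]:
                        values = config.N0 * np.exp(rng.normal(0.0, 1.0, size=times.size))
                        corrupted.append((pid, r, c))
                    else:
                        values = values_mat[r * config.cols + c]
                    plate_curves.append(
                        GrowthCurve(plate_id=pid, row=r, col=c, times=times, values=values)
                    )
            curves[pid] = plate_curves

    truth = SimulationTruth(
        effects=effects, bias_surface=bias, corrupted=corrupted, seed=config.seed
    )
    return curves, layouts, truth
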