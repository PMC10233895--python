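"""End-to-end screen analysis: curves -> doubling times -> normalized
phenotypes -> LPI calls -> hit lists and overlaps.

`analyze_screen` runs the whole chain in memory; `run_pipeline` is the
file-driven variant that reads curve/layout TSVs, writes every
intermediate table, and logs stage-level counts. Both are deterministic
given the same inputs and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .errors import PipelineError
from .gene_sets import GeneSet, overlap, read_gene_set
from .growth_curves import QCRules, process_plate
from .phenotype_calls import CallConfig, build_lpi_records
from .spatial_norm import DEFAULT_BANDWIDTH, normalize_screen

logger = logging.getLogger("colonyscreen")


@dataclass
class PipelineConfig:
    """Paths and parameters for a file-driven pipeline run."""

    curves_path: str | Path = ""
    layout_path: str | Path = ""
    blacklist_path: str | Path | None = None
    outdir: str | Path = "results"
    background_condition: str = "background"
    call: CallConfig = field(default_factory=CallConfig)
    qc: QCRules = field(default_factory=QCRules)
    median_window: int = 5
    mean_window: int = 5
    fit_window: int = 7
    min_r2: float = 0.95
    bandwidth: float = DEFAULT_BANDWIDTH
    universe_N: int | None = None  # default: number of scored strains
    compute_overlaps: bool = True


@dataclass
class ScreenResult:
    doubling: pd.DataFrame
    normalized: pd.DataFrame
    calls: pd.DataFrame
    hits: dict  # condition -> {"sensitive": [...], "resistant": [...]}
    excluded: set
    overlaps: list


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in records],
            "condition": [r.condition for r in records],
            "n_replicates": [len(r.lpi_replicates) for r in records],
            "lpi_mean": [r.lpi_mean for r in records],
            "t_stat": [r.t_stat for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "call": [r.call for r in records],
        }
    )


def analyze_screen(
    curves: dict,
    layouts: dict,
    config: PipelineConfig | None = None,
    blacklist: set | None = None,
    calibration=None,
) -> ScreenResult:
    """Run the full analysis on in-memory curves and layouts."""
    cfg = config or PipelineConfig()

    try:
        pieces = [
            process_plate(
                curves[pid],
                median_window=cfg.median_window,
                mean_window=cfg.mean_window,
                rules=cfg.qc,
                window=cfg.fit_window,
                min_r2=cfg.min_r2,
                calibration=calibration,
            )
            for pid in sorted(curves)
        ]
        doubling = pd.concat(pieces, ignore_index=True)
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError("growth", str(exc)) from exc
    n_curves = len(doubling)
    n_rejected = int((~doubling["qc_pass"]).sum())
    logger.info("growth: %d curves, %d QC-rejected", n_curves, n_rejected)

    try:
        normalized = normalize_screen(doubling, layouts, cfg.bandwidth)
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc
    logger.info("normalize: %d plates", normalized["plate_id"].nunique())

    try:
        records, excluded = build_lpi_records(
            normalized,
            background_condition=cfg.background_condition,
            config=cfg.call,
            blacklist=blacklist,
        )
    except Exception as exc:
        raise PipelineError("call", str(exc)) from exc
    calls = _records_to_frame(records)
    logger.info(
        "call: %d strains tested, %d excluded as slow growers",
        calls[calls["call"] != "excluded"]["strain_id"].nunique(),
        len(excluded),
    )

    hits: dict[str, dict[str, list[str]]] = {}
    for cond, g in calls.groupby("condition", sort=True):
        hits[cond] = {
            "sensitive": sorted(g.loc[g["call"] == "sensitive", "strain_id"]),
            "resistant": sorted(g.loc[g["call"] == "resistant", "strain_id"]),
        }
        logger.info(
            "hits[%s]: %d sensitive, %d resistant",
            cond,
            len(hits[cond]["sensitive"]),
            len(hits[cond]["resistant"]),
        )

    overlaps = []
    if cfg.compute_overlaps:
        universe = cfg.universe_N or int(
            calls.loc[calls["call"] != "excluded", "strain_id"].nunique()
        )
        conds = sorted(hits)
        for i, ca in enumerate(conds):
            for cb in conds[i + 1 :]:
                sa, sb = hits[ca]["sensitive"], hits[cb]["sensitive"]
                if sa and sb:
                    overlaps.append(
                        overlap(GeneSet(ca, sa), GeneSet(cb, sb), universe)
                    )

    return ScreenResult(doubling, normalized, calls, hits, excluded, overlaps)


def run_pipeline(config: PipelineConfig) -> ScreenResult:
    """File-driven pipeline: read inputs, analyze, write every stage table."""
    try:
        curves = io.read_curves(config.curves_path)
        layouts = io.read_layouts(config.layout_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    logger.info(
        "read: %d plates, %d curves",
        len(curves),
        sum(len(v) for v in curves.values()),
    )

    blacklist = None
    if config.blacklist_path:
        blacklist = set(read_gene_set(config.blacklist_path).members)

    result = analyze_screen(curves, layouts, config, blacklist=blacklist)

    outdir = Path(config.outdir)
    params = {
        "median_window": config.median_window,
        "mean_window": config.mean_window,
        "fit_window": config.fit_window,
        "min_r2": config.min_r2,
        "bandwidth": config.bandwidth,
        "alpha": config.call.alpha,
        "effect_threshold": config.call.effect_threshold,
    }
    io.write_table(result.doubling, outdir / "doubling_times.tsv", params)
    io.write_table(result.normalized, outdir / "normalized.tsv", params)
    io.write_table(result.calls, outdir / "calls.tsv", params)
    for cond, sets in result.hits.items():
        io.write_hit_list(sets["sensitive"], outdir / f"hits_{cond}_sensitive.txt")
        if sets["resistant"]:
            io.write_hit_list(sets["resistant"], outdir / f"hits_{cond}_resistant.txt")
    if result.overlaps:
        io.write_overlap_report(result.overlaps, outdir / "overlaps.json")
    return result
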