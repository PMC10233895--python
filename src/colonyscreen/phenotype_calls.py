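"""Strain-level phenotype calling via the Logarithmic Phenotypic Index.

Some deletion strains grow aberrantly already on background medium; the
LPI isolates the stressor-specific growth effect by differencing the
normalized log2 doubling times on stressor and background media:

    LPI = mean log2(D)_norm on stressor - mean log2(D)_norm on background

A positive LPI means the strain is more sensitive than the control to the
stressor (longer relative doubling time); negative means more resistant.

Calls use a dual criterion: a one-sample t-test of the replicate LPIs
against 0 with Benjamini-Hochberg FDR control at alpha (default 0.01)
across all tested strains of a condition, AND a strong-effect gate
|mean LPI| >= 2.5 log2 units (2^2.5 ~ 5.6-fold on doubling time). Strains
too slow-growing on background medium for a reliable estimate are
excluded up front.

Replicate-level LPIs are defined as each stressor replicate minus the
mean of the background replicates; plates are unpaired, so the background
enters only through its mean while the stressor replicates carry the
tested variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, MissingDataError

CALL_SENSITIVE = "sensitive"
CALL_RESISTANT = "resistant"
CALL_NONE = "none"
CALL_EXCLUDED = "excluded"


@dataclass
class CallConfig:
    alpha: float = 0.01  # FDR level
    effect_threshold: float = 2.5  # log2 units; 2^2.5 ~ 5.6-fold
    n_replicates: int = 3
    slow_grower_cutoff: float = 1.5  # log2 units on mean background log2D_norm
    symmetric_resistance: bool = True

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.effect_threshold <= 0:
            raise InvalidParameterError("effect_threshold must be > 0")


@dataclass
class LPIRecord:
    """Per-strain, per-condition LPI with test statistics and call."""

    strain_id: str
    condition: str
    lpi_replicates: list
    lpi_mean: float
    t_stat: float = math.nan
    p_value: float = math.nan
    q_value: float = math.nan
    call: str = CALL_NONE


def exclude_slow_growers(
    background_means: Mapping[str, float], cutoff: float = 1.5
) -> set:
    """Strains whose mean background log2(D)_norm is at or above ``cutoff``.

    Such strains grow so slowly on background medium that a stressor effect
    cannot be measured reliably; they receive no call. Non-finite means are
    ignored here (those strains fail later for missing data instead).
    """
    return {
        s for s, m in background_means.items() if np.isfinite(m) and m >= cutoff
    }


def compute_lpi(stressor_values: Sequence[float], background_values: Sequence[float]):
    """Replicate LPIs and their mean for one strain under one stressor.

    Each usable stressor replicate is differenced against the mean of the
    usable background replicates. Requires >= 2 stressor and >= 1
    background replicates, else :class:`MissingDataError`.
    """
    s = np.asarray(stressor_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    s = s[np.isfinite(s)]
    b = b[np.isfinite(b)]
    if s.size < 2 or b.size < 1:
        raise MissingDataError(
            f"need >= 2 stressor and >= 1 background replicates, got {s.size}/{b.size}"
        )
    lpi_replicates = s - b.mean()
    return list(lpi_replicates), float(s.mean() - b.mean())


def bh_fdr(p_values: Sequence[float], alpha: float = 0.01):
    """Benjamini-Hochberg step-up: q-values and rejection flags.

    q_i is the smallest FDR level at which p_i would be rejected
    (min over j with p_(j) >= p_(i) of p_(j)*m/rank(j), capped at 1);
    rejected iff q <= alpha. Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must be finite and in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


def _one_sample_t(values: np.ndarray):
    """Two-sided one-sample t-test against 0 with df = n - 1.

    Zero-variance replicates are a degenerate case: a nonzero mean with no
    spread is treated as p = 0 (infinitely strong evidence), a zero mean as
    p = 1.
    """
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    res = stats.ttest_1samp(values, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def call_phenotypes(records: Sequence[LPIRecord], config: CallConfig | None = None):
    """Fill in t, p, q and call for a batch of LPI records.

    Records already marked excluded are skipped. BH correction is applied
    separately within each condition, across all tested strains of that
    condition. A sensitive call requires q <= alpha and mean LPI >=
    effect_threshold; a resistant call (if enabled) requires q <= alpha and
    mean LPI <= -effect_threshold.
    """
    config = config or CallConfig()
    config.validate()

    by_condition: dict[str, list[LPIRecord]] = {}
    for rec in records:
        if rec.call == CALL_EXCLUDED:
            continue
        if len(rec.lpi_replicates) < 2:
            raise MissingDataError(
                f"strain {rec.strain_id!r} has < 2 LPI replicates"
            )
        by_condition.setdefault(rec.condition, []).append(rec)

    for cond_records in by_condition.values():
        for rec in cond_records:
            rec.t_stat, rec.p_value = _one_sample_t(
                np.asarray(rec.lpi_replicates, dtype=float)
            )
        q, rejected = bh_fdr([r.p_value for r in cond_records], config.alpha)
        for rec, qv, rej in zip(cond_records, q, rejected):
            rec.q_value = float(qv)
            if rej and rec.lpi_mean >= config.effect_threshold:
                rec.call = CALL_SENSITIVE
            elif (
                rej
                and config.symmetric_resistance
                and rec.lpi_mean <= -config.effect_threshold
            ):
                rec.call = CALL_RESISTANT
            else:
                rec.call = CALL_NONE
    return list(records)


def build_lpi_records(
    normalized,
    background_condition: str = "background",
    config: CallConfig | None = None,
    blacklist: set | None = None,
):
    """Aggregate a normalized screen table into called LPI records.

    ``normalized`` is the per-colony table from spatial normalization
    (columns strain_id, is_control, condition, replicate, log2D_norm,
    qc_pass). Control colonies and blacklisted strains are dropped; slow
    growers on background medium are marked excluded; every remaining
    strain x stressor condition becomes one LPI record; strains with too
    few usable replicates are reported uncalled (call "none", NaN stats).
    """
    config = config or CallConfig()
    blacklist = {s.upper() for s in (blacklist or set())}

    df = normalized[~normalized["is_control"]].copy()
    df = df[df["strain_id"].notna()]
    if blacklist:
        df = df[~df["strain_id"].str.upper().isin(blacklist)]
    usable = df[df["qc_pass"] & np.isfinite(df["log2D_norm"])]

    bg = usable[usable["condition"] == background_condition]
    bg_values = {
        s: g["log2D_norm"].to_numpy() for s, g in bg.groupby("strain_id", sort=True)
    }
    bg_means = {s: float(v.mean()) for s, v in bg_values.items()}
    excluded = exclude_slow_growers(bg_means, config.slow_grower_cutoff)

    stressors = [
        c for c in usable["condition"].unique() if c != background_condition
    ]
    records: list[LPIRecord] = []
    all_strains = sorted(df["strain_id"].unique())
    for cond in sorted(stressors):
        sub = usable[usable["condition"] == cond]
        values = {
            s: g["log2D_norm"].to_numpy() for s, g in sub.groupby("strain_id", sort=True)
        }
        for strain in all_strains:
            if strain in excluded:
                records.append(
                    LPIRecord(strain, cond, [], math.nan, call=CALL_EXCLUDED)
                )
                continue
            try:
                reps, mean = compute_lpi(
                    values.get(strain, []), bg_values.get(strain, [])
                )
            except MissingDataError:
                records.append(LPIRecord(strain, cond, [], math.nan, call=CALL_NONE))
                continue
            records.append(LPIRecord(strain, cond, reps, mean))

    testable = [r for r in records if r.call != CALL_EXCLUDED and len(r.lpi_replicates) >= 2]
    call_phenotypes(testable, config)
    return records, excluded
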