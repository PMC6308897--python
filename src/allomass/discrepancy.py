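"""Prediction-discrepancy analysis, including cross-region parameter transfer.

The discrepancy of a prediction is the log response ratio
``delta = log10(m_pred / m_obs)``: zero means predicted and observed masses
are identical, positive means overestimation, negative underestimation.
Averaging delta and back-transforming gives the geometric-mean ratio of
predicted to observed mass (e.g. 0.77 = 23% average underestimation).

The disjunct analysis applies the two all-taxa model families (LR and LWR)
to each region twice — once with that region's own (nondisjunct) parameters
and once with the other region's (disjunct) parameters — and regresses the
per-individual discrepancy on log10 body length to expose size-dependent
bias in cross-region parameter transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError
from .param_db import ParameterDatabase, ParameterSet
from .records import REGIONS, normalize_name


@dataclass(frozen=True)
class DiscrepancyResult:
    """Per-individual discrepancies and summaries for one region x mode."""

    target_region: str
    application_mode: str  # "nondisjunct" | "disjunct"
    parameter_region: str
    model_family: str
    deltas: np.ndarray
    log10_lengths: np.ndarray
    geometric_mean_ratio: float
    percent_bias: float
    trend_intercept: float
    trend_slope: float

    @property
    def n(self) -> int:
        return self.deltas.size


def prediction_discrepancy(m_pred, m_obs):
    """Log response ratio log10(m_pred / m_obs); scalar or elementwise."""
    m_pred = np.asarray(m_pred, float)
    m_obs = np.asarray(m_obs, float)
    if np.any(m_pred <= 0) or np.any(m_obs <= 0):
        raise ValidationError("masses must be positive")
    out = np.log10(m_pred) - np.log10(m_obs)
    return float(out) if out.ndim == 0 else out


def geometric_mean_ratio(deltas) -> tuple[float, float]:
    """(ratio, percent_bias) from per-individual log response ratios.

    ratio = 10**mean(delta); percent_bias = 100*(ratio - 1), so a ratio of
    0.77 reads as -23% (average underestimation) and 1.29 as +29%.
    """
    deltas = np.asarray(deltas, float)
    if deltas.size == 0:
        raise UsageError("need at least one discrepancy value")
    ratio = float(10.0 ** deltas.mean())
    return ratio, 100.0 * (ratio - 1.0)


def discrepancy_trend(deltas, log10_lengths) -> tuple[float, float]:
    """OLS fit of discrepancy on log10 body length: (intercept, slope)."""
    deltas = np.asarray(deltas, float)
    x = np.asarray(log10_lengths, float)
    if deltas.size < 3:
        raise UsageError("need at least three points for a trend")
    if np.ptp(x) == 0:
        raise ValidationError("log10 lengths are constant; trend undefined")
    fit = stats.linregress(x, deltas)
    return float(fit.intercept), float(fit.slope)


def _region_params(
    params: ParameterDatabase | dict[str, ParameterSet], model_family: str
) -> dict[str, ParameterSet]:
    if isinstance(params, ParameterDatabase):
        return {r: params.lookup(model_family, region=r) for r in REGIONS}
    return {normalize_name(k): v for k, v in params.items()}


def disjunct_comparison(
    records: pd.DataFrame,
    params: ParameterDatabase | dict[str, ParameterSet],
    model_family: str = "LR",
) -> list[DiscrepancyResult]:
    """Nondisjunct vs disjunct discrepancy for each region in ``records``.

    ``records`` needs columns ``region``, ``length_mm``, ``mass_mg`` (and
    ``width_mm`` for family LWR). ``params`` is a parameter database or a
    mapping region -> :class:`ParameterSet` of the chosen all-taxa family.
    Returns one result per (target region, mode), nondisjunct first.
    """
    if model_family not in ("LR", "LWR"):
        raise UsageError("disjunct comparison is defined for the all-taxa families LR and LWR")
    by_region = _region_params(params, model_family)
    df = records[records["mass_mg"].notna()].copy()
    if df.empty:
        raise UsageError("no records with observed mass")
    df["region"] = df["region"].map(normalize_name)
    regions = sorted(df["region"].dropna().unique())
    missing = [r for r in regions if r not in by_region]
    if missing:
        raise UsageError(f"no {model_family} parameters for region(s) {missing}")

    results = []
    for target in regions:
        sub = df[df["region"] == target]
        log_len = np.log10(sub["length_mm"].to_numpy(float))
        log_obs = np.log10(sub["mass_mg"].to_numpy(float))
        for mode in ("nondisjunct", "disjunct"):
            source = target if mode == "nondisjunct" else _other_region(target)
            if source not in by_region:
                raise UsageError(f"no {model_family} parameters for region {source!r}")
            p = by_region[source]
            log_pred = p.intercept + p.slope_length * log_len
            if p.uses_width:
                widths = sub["width_mm"].to_numpy(float)
                if np.any(~np.isfinite(widths)) or np.any(widths <= 0):
                    raise UsageError("family LWR requires a positive width for every record")
                log_pred = log_pred + p.slope_width * np.log10(widths)
            deltas = log_pred - log_obs
            ratio, pct = geometric_mean_ratio(deltas)
            intercept, slope = discrepancy_trend(deltas, log_len)
            results.append(
                DiscrepancyResult(
                    target_region=target,
                    application_mode=mode,
                    parameter_region=source,
                    model_family=model_family,
                    deltas=deltas,
                    log10_lengths=log_len,
                    geometric_mean_ratio=ratio,
                    percent_bias=pct,
                    trend_intercept=intercept,
                    trend_slope=slope,
                )
            )
    return results


def _other_region(region: str) -> str:
    return REGIONS[1] if region == REGIONS[0] else REGIONS[0]


def summary_table(results: list[DiscrepancyResult]) -> pd.DataFrame:
    """Summaries as a flat table (one row per region x mode)."""
    return pd.DataFrame(
        {
            "region": [r.target_region for r in results],
            "mode": [r.application_mode for r in results],
            "parameter_region": [r.parameter_region for r in results],
            "model_family": [r.model_family for r in results],
            "n": [r.n for r in results],
            "geometric_mean_ratio": [r.geometric_mean_ratio for r in results],
            "percent_bias": [r.percent_bias for r in results],
            "trend_intercept": [r.trend_intercept for r in results],
            "trend_slope": [r.trend_slope for r in results],
        }
    )
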