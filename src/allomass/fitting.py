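"""Refitting the eight-model comparison suite on a morphometric dataset.

All eight model families are ordinary least squares on the log10 scale.
Grouped families (by taxon, region, or the combined TaxReg factor) give
every grouping level its own intercept and slope(s) — a full interaction of
the factor with each continuous predictor — which is estimated here as
independent per-level regressions; the pooled residual sum of squares,
likelihood, BIC and LOOCV errors are identical to the single-design
formulation. Because not all taxa occur in both regions, taxon and region
cannot be crossed factorially; the combined TaxReg factor carries one level
per observed taxon x region combination instead.

Model comparison follows the information-theoretic workflow: BIC (Gaussian
log-likelihood with all coefficients plus the residual variance counted),
differences from the suite minimum, BIC weights, R² as 1 - RSS/TSS on the
log10 response, and leave-one-out cross-validation mean squared error
computed exactly via the PRESS/hat-matrix identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FittingError, UsageError, ValidationError
from .param_db import ParameterSet
from .records import MODEL_PREFERENCE, MorphometricRecord, normalize_name


@dataclass(frozen=True)
class ModelSpec:
    """Design of one model family: predictors and grouping factor."""

    model_id: str
    use_width: bool
    grouping: str  # "taxreg" | "taxon" | "region" | "none"

    def __post_init__(self) -> None:
        if self.grouping not in ("taxreg", "taxon", "region", "none"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")

    @property
    def n_slopes(self) -> int:
        return 2 if self.use_width else 1


#: The eight families of the comparison suite, keyed by model id.
MODEL_SPECS: dict[str, ModelSpec] = {
    "LWTR": ModelSpec("LWTR", True, "taxreg"),
    "LWT": ModelSpec("LWT", True, "taxon"),
    "LWR": ModelSpec("LWR", True, "region"),
    "LW": ModelSpec("LW", True, "none"),
    "LTR": ModelSpec("LTR", False, "taxreg"),
    "LT": ModelSpec("LT", False, "taxon"),
    "LR": ModelSpec("LR", False, "region"),
    "L": ModelSpec("L", False, "none"),
}


@dataclass(frozen=True)
class FitResult:
    """One fitted family's coefficients and comparison metrics."""

    model_id: str
    parameters: tuple[ParameterSet, ...]
    n_obs: int
    k_params: int
    bic: float
    r2: float
    loocv_mse: float
    rss: float
    smearing_factor: float
    delta_bic: float = float("nan")
    bic_weight: float = float("nan")


def build_taxreg(taxon: str | None, region: str | None) -> str:
    """Combined taxon x region factor level, e.g. ``"Araneae:temperate"``."""
    if taxon is None or region is None or not str(taxon).strip() or not str(region).strip():
        raise UsageError(
            f"TaxReg requires both taxon and region, got taxon={taxon!r}, region={region!r}"
        )
    return f"{str(taxon).strip()}:{normalize_name(region)}"


def preprocess(
    data: pd.DataFrame | list[MorphometricRecord], require_width: bool = False
) -> pd.DataFrame:
    """Filter and log10-transform a morphometric table for fitting.

    Larval records are excluded, as are records without an observed mass;
    with ``require_width=True`` (the width-model suite) records lacking a
    width measurement are dropped too. The returned frame carries
    ``log10_length``, ``log10_width`` and ``log10_mass`` columns; dropped
    counts are recorded in ``df.attrs["filter_counts"]``.
    """
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in data],
                "taxon": [r.taxon for r in data],
                "region": [r.region for r in data],
                "length_mm": [r.body_length for r in data],
                "width_mm": [r.body_width for r in data],
                "mass_mg": [r.body_mass for r in data],
                "is_larva": [r.is_larva for r in data],
            }
        )
    n0 = len(df)
    if "is_larva" in df.columns:
        larvae = df["is_larva"].fillna(False).astype(bool)
    else:
        larvae = pd.Series(False, index=df.index)
    df = df[~larvae]
    n_larvae = n0 - len(df)

    has_mass = df["mass_mg"].notna()
    n_no_mass = int((~has_mass).sum())
    df = df[has_mass]

    n_no_width = 0
    if require_width:
        has_width = df["width_mm"].notna()
        n_no_width = int((~has_width).sum())
        df = df[has_width]

    if df.empty:
        raise UsageError("no records left after filtering larvae/missing measurements")
    bad = df[(df["length_mm"] <= 0) | (df["mass_mg"] <= 0)]
    if not bad.empty:
        raise ValidationError(f"nonpositive length/mass in rows {list(bad.index)[:5]}")

    df = df.copy()
    df["log10_length"] = np.log10(df["length_mm"].astype(float))
    df["log10_mass"] = np.log10(df["mass_mg"].astype(float))
    with np.errstate(invalid="ignore"):
        df["log10_width"] = np.log10(df["width_mm"].astype(float))
    df.attrs["filter_counts"] = {
        "input": n0,
        "larvae_dropped": n_larvae,
        "missing_mass_dropped": n_no_mass,
        "missing_width_dropped": n_no_width,
        "retained": len(df),
    }
    return df


def _group_labels(df: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    if spec.grouping == "none":
        return pd.Series("", index=df.index)
    if spec.grouping == "taxreg":
        return pd.Series(
            [build_taxreg(t, r) for t, r in zip(df["taxon"], df["region"])],
            index=df.index,
        )
    col = spec.grouping
    labels = df[col]
    if labels.isna().any():
        raise UsageError(f"model {spec.model_id} requires a known {col} for every record")
    return labels.astype(str)


def _param_key(spec: ModelSpec, level: str) -> dict:
    if spec.grouping == "taxreg":
        taxon, region = level.rsplit(":", 1)
        return {"taxon": taxon, "region": region}
    if spec.grouping == "taxon":
        return {"taxon": level, "region": None}
    if spec.grouping == "region":
        return {"taxon": None, "region": level}
    return {"taxon": None, "region": None}


def _fit_groups(df: pd.DataFrame, spec: ModelSpec):
    """Per-level OLS fits; returns (parameters, residuals, hat diagonal)."""
    cols = ["log10_length"] + (["log10_width"] if spec.use_width else [])
    if spec.use_width and df["log10_width"].isna().any():
        raise UsageError(
            f"model {spec.model_id} requires a width for every record; "
            "preprocess with require_width=True"
        )
    labels = _group_labels(df, spec)
    min_n = spec.n_slopes + 2
    params: list[ParameterSet] = []
    resid = np.empty(len(df))
    hat = np.empty(len(df))
    positions = pd.Series(np.arange(len(df)), index=df.index)
    for level, sub in df.groupby(labels, sort=True):
        if len(sub) < min_n:
            raise FittingError(
                f"grouping level {level!r} has {len(sub)} observations; "
                f"model {spec.model_id} needs at least {min_n}"
            )
        X = sm.add_constant(sub[cols].to_numpy(float), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FittingError(f"rank-deficient design in grouping level {level!r}")
        fit = sm.OLS(sub["log10_mass"].to_numpy(float), X).fit()
        idx = positions.loc[sub.index].to_numpy()
        resid[idx] = fit.resid
        h = fit.get_influence().hat_matrix_diag
        if np.any(h > 1 - 1e-10):
            raise FittingError(
                f"leave-one-out fold rank-deficient in grouping level {level!r}"
            )
        hat[idx] = h
        coefs = fit.params
        params.append(
            ParameterSet(
                model_id=spec.model_id,
                intercept=float(coefs[0]),
                slope_length=float(coefs[1]),
                slope_width=float(coefs[2]) if spec.use_width else None,
                **_param_key(spec, level),
            )
        )
    return params, resid, hat


def r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination, 1 - RSS/TSS, on the supplied response."""
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValidationError("response has zero variance; R^2 undefined")
    rss = float(np.sum((y - fitted) ** 2))
    return 1.0 - rss / tss


def smearing_factor(residuals: np.ndarray) -> float:
    """Duan smearing estimator on the log10 scale: mean of 10**residual.

    Multiplying a naively back-transformed prediction by this factor
    corrects the retransformation bias of ``10**E[log10 M]``.
    """
    residuals = np.asarray(residuals, float)
    if residuals.size == 0:
        raise UsageError("need at least one residual")
    return float(np.mean(10.0 ** residuals))


def fit_single(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one family; delta_bic/bic_weight are NaN until suite assembly."""
    params, resid, hat = _fit_groups(df, spec)
    n = len(df)
    y = df["log10_mass"].to_numpy(float)
    rss = float(np.sum(resid ** 2))
    if rss <= 0:
        # perfect fit: log-likelihood unbounded; report -inf BIC
        loglik = math.inf
    else:
        loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    p = len(params) * (1 + spec.n_slopes)
    k = p + 1  # + residual variance
    bic = -2.0 * loglik + k * math.log(n)
    press = resid / (1.0 - hat)
    return FitResult(
        model_id=spec.model_id,
        parameters=tuple(params),
        n_obs=n,
        k_params=k,
        bic=bic,
        r2=r_squared(y, y - resid),
        loocv_mse=float(np.mean(press ** 2)),
        rss=rss,
        smearing_factor=smearing_factor(resid),
    )


def bic_weights(bic_values) -> np.ndarray:
    """Evidence weights exp(-d_i/2) / sum_j exp(-d_j/2), d_i = BIC_i - min BIC.

    Accepts raw BIC values or precomputed differences (the weights are
    invariant to any constant shift). Computed in shifted form so very
    large differences underflow to 0 rather than overflow.
    """
    values = np.asarray(bic_values, float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValidationError("bic_weights requires a nonempty finite array")
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def loocv_mse(df: pd.DataFrame, spec: ModelSpec) -> float:
    """Leave-one-out CV mean squared error of log10 mass for one family.

    Uses the exact PRESS identity e_i / (1 - h_ii); identical to refitting
    the model n times with one observation held out each time.
    """
    _, resid, hat = _fit_groups(df, spec)
    return float(np.mean((resid / (1.0 - hat)) ** 2))


def fit_model_suite(
    df: pd.DataFrame, specs: list[ModelSpec] | None = None
) -> list[FitResult]:
    """Fit a suite of families on one preprocessed table and compare them.

    Returns results sorted by BIC ascending (ties broken by model id), with
    BIC differences from the suite minimum and BIC weights filled in.
    """
    if specs is None:
        specs = [MODEL_SPECS[m] for m in MODEL_PREFERENCE]
    if not specs:
        raise UsageError("empty model suite")
    results = [fit_single(df, spec) for spec in specs]
    bics = np.array([r.bic for r in results])
    if np.all(np.isfinite(bics)):
        weights = bic_weights(bics)
        delta = bics - bics.min()
    else:  # a perfect fit dominates; split weight among -inf ties
        best = np.isneginf(bics)
        weights = best / best.sum()
        delta = np.where(best, 0.0, np.inf)
    results = [
        replace(r, delta_bic=float(d), bic_weight=float(w))
        for r, d, w in zip(results, delta, weights)
    ]
    return sorted(results, key=lambda r: (r.bic, r.model_id))


def comparison_table(results: list[FitResult]) -> pd.DataFrame:
    """Suite results as a model-comparison table (one row per family)."""
    return pd.DataFrame(
        {
            "model_id": [r.model_id for r in results],
            "n_obs": [r.n_obs for r in results],
            "k_params": [r.k_params for r in results],
            "bic": [r.bic for r in results],
            "delta_bic": [r.delta_bic for r in results],
            "bic_weight": [r.bic_weight for r in results],
            "r2": [r.r2 for r in results],
            "loocv_mse": [r.loocv_mse for r in results],
        }
    )
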