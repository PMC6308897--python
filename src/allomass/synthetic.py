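"""Synthetic morphometric communities with known allometric truth.

The generator emulates the log-linear length-width-mass structure the
regression suite assumes: per individual,

- log10 L ~ Uniform over the configured length range (log10 scale), so the
  regression domain is covered evenly;
- log10 W = alpha_w + beta_w * log10 L + N(0, sigma_w) — an isometric width
  model (beta_w = 1) with a typical arthropod width/length ratio by default;
- log10 M = a + b_len * log10 L [+ b_wid * log10 W] + N(0, sigma_m), with
  (a, b_len, b_wid) taken from a generating parameter set (defaults: the
  builtin taxon x region equations).

Noise is Gaussian on the log10 scale — the implicit error model of the
OLS-on-logs workflow — so lengths, widths and masses are strictly positive
by construction. Output is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .param_db import ParameterDatabase, ParameterSet, load_default_parameters
from .records import normalize_name


def default_noise_sd() -> float:
    """Default mass noise SD on the log10 scale, ~0.126.

    The square root of the best family's published LOOCV prediction error
    (0.016 squared-log10 units), so communities simulated at this noise
    level reproduce that family's prediction-error scale.
    """
    from .param_db import published_model_comparison

    table = published_model_comparison()
    mse = float(table.loc[table["model_id"] == "LWTR", "prediction_error"].iloc[0])
    return math.sqrt(mse)


@dataclass(frozen=True)
class WidthModel:
    """log10 W = alpha + beta * log10 L + N(0, sigma)."""

    alpha: float = math.log10(0.35)  # width ~ 35% of length
    beta: float = 1.0
    sigma: float = 0.10

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass(frozen=True)
class GroupConfig:
    """One simulated taxon x region group."""

    taxon: str
    region: str
    n: int
    length_range: tuple[float, float]  # mm
    n_larvae: int = 0  # extra records flagged as larvae
    width_missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValidationError(f"length_range must satisfy 0 < min <= max, got {self.length_range}")
        if not (0 <= self.width_missing_fraction <= 1):
            raise ValidationError("width_missing_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating truth for a simulated community.

    ``parameters`` maps each group to its generating equation; by default
    the builtin taxon x region (LWTR) equations are used, with sampling
    ranges from the builtin metadata when ``groups`` is omitted downstream.
    """

    groups: tuple[GroupConfig, ...]
    parameters: dict[tuple[str, str], ParameterSet] | None = None
    width_model: WidthModel = field(default_factory=WidthModel)
    mass_noise_sd: float | None = None  # None -> default_noise_sd()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("need at least one group")
        if self.mass_noise_sd is not None and self.mass_noise_sd < 0:
            raise ValidationError("mass_noise_sd must be >= 0")


def default_community_config(
    seed: int = 0,
    n_per_group: int = 50,
    db: ParameterDatabase | None = None,
    mass_noise_sd: float | None = None,
) -> SyntheticConfig:
    """A community spanning every builtin taxon x region combination.

    Group sampling ranges are the published per-combination length ranges;
    generating truths are the builtin taxon x region equations.
    """
    db = db or load_default_parameters()
    groups = []
    params: dict[tuple[str, str], ParameterSet] = {}
    for p in sorted(db, key=lambda p: (p.taxon or "", p.region or "")):
        if p.model_id != "LWTR":
            continue
        meta = db.validity_range(p.taxon, p.region)
        groups.append(
            GroupConfig(
                taxon=p.taxon,
                region=p.region,
                n=n_per_group,
                length_range=meta.length_range,
            )
        )
        params[(normalize_name(p.taxon), normalize_name(p.region))] = p
    return SyntheticConfig(
        groups=tuple(groups), parameters=params, mass_noise_sd=mass_noise_sd, seed=seed
    )


def _generating_params(
    config: SyntheticConfig, group: GroupConfig
) -> ParameterSet:
    key = (normalize_name(group.taxon), normalize_name(group.region))
    if config.parameters is not None:
        table = {
            (normalize_name(t), normalize_name(r)): p
            for (t, r), p in config.parameters.items()
        }
        if key not in table:
            raise UsageError(f"no generating parameters for group {group.taxon}/{group.region}")
        return table[key]
    db = load_default_parameters()
    try:
        return db.lookup("LWTR", group.taxon, group.region)
    except LookupError as exc:
        raise UsageError(
            f"no builtin generating parameters for group {group.taxon}/{group.region}"
        ) from exc


def generate_community(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a morphometric table from a :class:`SyntheticConfig`.

    Returns the standard morphometric frame (``individual_id``, ``taxon``,
    ``family``, ``region``, ``length_mm``, ``width_mm``, ``mass_mg``,
    ``is_larva``); the generating truth is attached as
    ``df.attrs["generating_truth"]``.
    """
    rng = np.random.default_rng(config.seed)
    sigma_m = config.mass_noise_sd if config.mass_noise_sd is not None else default_noise_sd()
    wm = config.width_model
    frames = []
    counter = 0
    for group in config.groups:
        p = _generating_params(config, group)
        n_total = group.n + group.n_larvae
        lo, hi = group.length_range
        log_len = rng.uniform(math.log10(lo), math.log10(hi), size=n_total)
        log_wid = wm.alpha + wm.beta * log_len + rng.normal(0.0, wm.sigma, size=n_total)
        log_mass = p.intercept + p.slope_length * log_len
        if p.uses_width:
            log_mass = log_mass + p.slope_width * log_wid
        log_mass = log_mass + rng.normal(0.0, sigma_m, size=n_total)

        width = 10.0 ** log_wid
        n_missing = int(round(group.width_missing_fraction * n_total))
        if n_missing:
            missing_idx = rng.choice(n_total, size=n_missing, replace=False)
            width[missing_idx] = np.nan

        frames.append(
            pd.DataFrame(
                {
                    "individual_id": [f"sim{counter + i:06d}" for i in range(n_total)],
                    "taxon": group.taxon,
                    "family": None,
                    "region": normalize_name(group.region),
                    "length_mm": 10.0 ** log_len,
                    "width_mm": width,
                    "mass_mg": 10.0 ** log_mass,
                    "is_larva": [i >= group.n for i in range(n_total)],
                }
            )
        )
        counter += n_total
    df = pd.concat(frames, ignore_index=True)
    df.attrs["generating_truth"] = describe_truth(config, sigma_m)
    return df


def describe_truth(config: SyntheticConfig, sigma_m: float | None = None) -> dict:
    """JSON-serializable record of the generating truth (for sidecar files)."""
    sigma_m = sigma_m if sigma_m is not None else (
        config.mass_noise_sd if config.mass_noise_sd is not None else default_noise_sd()
    )
    groups = []
    for g in config.groups:
        p = _generating_params(config, g)
        groups.append(
            {
                "taxon": g.taxon,
                "region": normalize_name(g.region),
                "n": g.n,
                "n_larvae": g.n_larvae,
                "length_range_mm": list(g.length_range),
                "width_missing_fraction": g.width_missing_fraction,
                "intercept": p.intercept,
                "slope_length": p.slope_length,
                "slope_width": p.slope_width,
                "model_id": p.model_id,
            }
        )
    return {
        "seed": config.seed,
        "mass_noise_sd": sigma_m,
        "width_model": {
            "alpha": config.width_model.alpha,
            "beta": config.width_model.beta,
            "sigma": config.width_model.sigma,
        },
        "groups": groups,
    }
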