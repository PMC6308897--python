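"""Core domain types: individual morphometric records and model identifiers.

All measurements use fixed units: body length and maximum body width in mm,
live body mass in mg. Masses, lengths and regression arithmetic downstream
operate on the log10 scale, where the allometric power law
``M = 10^a * L^b_len * W^b_wid`` becomes linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: The eight model families, ordered by decreasing predictive information
#: (the model-comparison ranking): width-bearing models first, then
#: taxon/region-bearing length-only models, ending with the plain
#: length-only regression which is always applicable.
MODEL_PREFERENCE: tuple[str, ...] = (
    "LWTR", "LWT", "LWR", "LW", "LTR", "LT", "LR", "L",
)

MODEL_IDS = frozenset(MODEL_PREFERENCE)

#: Controlled vocabulary for geographic region.
REGIONS = ("temperate", "tropical")

#: Model families whose equation includes a body-width term.
WIDTH_MODELS = frozenset({"LWTR", "LWT", "LWR", "LW"})
#: Model families with taxon-specific parameters.
TAXON_MODELS = frozenset({"LWTR", "LWT", "LTR", "LT"})
#: Model families with region-specific parameters.
REGION_MODELS = frozenset({"LWTR", "LWR", "LTR", "LR"})


def normalize_name(name: str | None) -> str | None:
    """Whitespace-normalize and casefold a taxon/region name for matching."""
    if name is None:
        return None
    collapsed = " ".join(str(name).split())
    return collapsed.casefold() if collapsed else None


def _positive(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{what} must be a finite positive number, got {value!r}")
    return value


@dataclass(frozen=True)
class MorphometricRecord:
    """One measured individual.

    Parameters
    ----------
    individual_id : str
        Opaque label, unique within a table.
    body_length : float
        Body length in mm (appendages excluded), > 0.
    taxon, family, region : str, optional
        Order-level taxon, family, and geographic region (``temperate`` or
        ``tropical``); ``None`` when unknown.
    body_width : float, optional
        Maximum body width in mm, > 0 when present.
    body_mass : float, optional
        Observed live body mass in mg, > 0 when present.
    is_larva : bool
        Larval individuals are excluded from regression fitting.
    """

    individual_id: str
    body_length: float
    taxon: str | None = None
    family: str | None = None
    region: str | None = None
    body_width: float | None = None
    body_mass: float | None = None
    is_larva: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "body_length", _positive(self.body_length, "body_length"))
        if self.body_width is not None:
            object.__setattr__(self, "body_width", _positive(self.body_width, "body_width"))
        if self.body_mass is not None:
            object.__setattr__(self, "body_mass", _positive(self.body_mass, "body_mass"))
        region = normalize_name(self.region)
        if region is not None and region not in REGIONS:
            raise ValidationError(
                f"region must be one of {REGIONS} or unknown, got {self.region!r}"
            )
        object.__setattr__(self, "region", region)


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of predicting one individual's live body mass.

    ``mass_pred`` equals ``10**log10_mass_pred`` unless a retransformation
    (smearing) correction was applied. ``flags`` may contain
    ``extrapolated_length``, ``extrapolated_width``,
    ``nonsignificant_coefficient`` and ``fallback_model``.
    """

    individual_id: str
    log10_mass_pred: float
    mass_pred: float
    model_used: str
    parameter_key: tuple[str | None, str | None]
    flags: frozenset[str] = field(default_factory=frozenset)
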