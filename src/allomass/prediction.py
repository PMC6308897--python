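"""Live body-mass prediction from length/width measurements.

The prediction engine evaluates the allometric regression on the log10
scale, ``log10 M = a + b_len*log10 L [+ b_wid*log10 W]``, choosing the most
informative model family the record's fields (and the parameter database)
support, in the fixed preference order
LWTR > LWT > LWR > LW > LTR > LT > LR > L — width-bearing models outrank
taxon-bearing length-only ones, mirroring the published model comparison.
"""

from __future__ import annotations

import math

from .errors import ParameterLookupError, UsageError, ValidationError
from .param_db import ParameterDatabase, ParameterSet, TaxonRegionMetadata
from .records import (
    MODEL_PREFERENCE,
    MorphometricRecord,
    PredictionResult,
    REGION_MODELS,
    TAXON_MODELS,
    WIDTH_MODELS,
)


def predict_log10_mass(
    params: ParameterSet, length: float, width: float | None = None
) -> float:
    """Evaluate one regression equation; returns log10 body mass (mg).

    ``length`` and ``width`` are in mm; ``width`` must be supplied exactly
    when ``params`` carries a width slope.
    """
    if not (isinstance(length, (int, float)) and math.isfinite(length) and length > 0):
        raise ValidationError(f"length must be finite and > 0, got {length!r}")
    if params.uses_width:
        if width is None:
            raise UsageError(f"model {params.model_id} requires a body width")
        if not (math.isfinite(width) and width > 0):
            raise ValidationError(f"width must be finite and > 0, got {width!r}")
    elif width is not None:
        raise UsageError(f"model {params.model_id} does not take a body width")

    y = params.intercept + params.slope_length * math.log10(length)
    if params.uses_width:
        y += params.slope_width * math.log10(width)
    return y


def select_model(
    has_width: bool,
    taxon_known: bool,
    region_known: bool,
    db_has_taxon_region_entry: bool = True,
) -> str:
    """First applicable model family in the fixed preference order.

    ``db_has_taxon_region_entry`` states whether the parameter database holds
    entries for this record's taxon (and taxon x region combination where
    required); when False, taxon-bearing families are skipped. The plain
    length-only model L is always applicable, so a model is always returned.
    """
    for model_id in MODEL_PREFERENCE:
        if model_id in WIDTH_MODELS and not has_width:
            continue
        if model_id in TAXON_MODELS and not (taxon_known and db_has_taxon_region_entry):
            continue
        if model_id in REGION_MODELS and not region_known:
            continue
        return model_id
    raise AssertionError("unreachable: model L is always applicable")


def flag_extrapolation(
    record: MorphometricRecord, metadata: TaxonRegionMetadata
) -> set[str]:
    """Flags for measurements outside the ranges the parameters were fitted on.

    Intervals are closed: a value equal to the published minimum or maximum
    is in range. Never raises for out-of-range values.
    """
    flags: set[str] = set()
    lo, hi = metadata.length_range
    if not (lo <= record.body_length <= hi):
        flags.add("extrapolated_length")
    width_range = getattr(metadata, "width_range", None)
    if width_range is not None and record.body_width is not None:
        wlo, whi = width_range
        if not (wlo <= record.body_width <= whi):
            flags.add("extrapolated_width")
    return flags


def predict_mass(
    record: MorphometricRecord,
    db: ParameterDatabase,
    model_override: str | None = None,
    bias_correction: str = "none",
    smearing_factor: float | None = None,
) -> PredictionResult:
    """Predict one individual's live body mass in mg.

    Walks the model preference cascade (unless ``model_override`` pins a
    family), evaluates the equation, and back-transforms with ``10**x``.
    With ``bias_correction="smearing"`` the back-transformed mass is
    multiplied by a smearing factor (mean of ``10**residual`` from the fit
    that produced the parameters, see :func:`allomass.fitting.smearing_factor`);
    the default is the naive back-transform.

    Flags attached to the result:

    - ``fallback_model`` — a more informative family was skipped only
      because its taxon (x region) entry is absent from the database;
    - ``nonsignificant_coefficient`` — a used coefficient carries no
      significance star;
    - ``extrapolated_length`` — length outside the published sampling range.
    """
    if bias_correction not in ("none", "smearing"):
        raise UsageError(f"unknown bias_correction {bias_correction!r}")
    if bias_correction == "smearing" and smearing_factor is None:
        raise UsageError("bias_correction='smearing' requires a smearing_factor")

    params, fell_back = _resolve_parameters(record, db, model_override)
    width = record.body_width if params.uses_width else None
    log10_mass = predict_log10_mass(params, record.body_length, width)
    mass = 10.0 ** log10_mass
    if bias_correction == "smearing":
        mass *= smearing_factor

    flags: set[str] = set()
    if fell_back:
        flags.add("fallback_model")
    if params.has_nonsignificant_coefficient:
        flags.add("nonsignificant_coefficient")
    if record.taxon is not None and record.region is not None:
        try:
            meta = db.validity_range(record.taxon, record.region)
        except ParameterLookupError:
            pass
        else:
            flags |= flag_extrapolation(record, meta)

    return PredictionResult(
        individual_id=record.individual_id,
        log10_mass_pred=log10_mass,
        mass_pred=mass,
        model_used=params.model_id,
        parameter_key=(params.taxon, params.region),
        flags=frozenset(flags),
    )


def _resolve_parameters(
    record: MorphometricRecord, db: ParameterDatabase, model_override: str | None
) -> tuple[ParameterSet, bool]:
    candidates = (model_override,) if model_override else MODEL_PREFERENCE
    fell_back = False
    for model_id in candidates:
        if model_id in WIDTH_MODELS and record.body_width is None:
            if model_override:
                raise UsageError(f"model {model_id} requires a body width measurement")
            continue
        if model_id in TAXON_MODELS and record.taxon is None:
            if model_override:
                raise UsageError(f"model {model_id} requires a known taxon")
            continue
        if model_id in REGION_MODELS and record.region is None:
            if model_override:
                raise UsageError(f"model {model_id} requires a known region")
            continue
        taxon = record.taxon if model_id in TAXON_MODELS else None
        region = record.region if model_id in REGION_MODELS else None
        try:
            return db.lookup(model_id, taxon, region), fell_back
        except ParameterLookupError:
            if model_override:
                raise
            # record had the fields; only the database entry is missing
            fell_back = True
    raise UsageError(
        f"no applicable model for record {record.individual_id!r}"
    )  # pragma: no cover - L always present in a well-formed database
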